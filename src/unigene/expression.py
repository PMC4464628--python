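"""Expression profiling: FPKM, exact negative-binomial differential
expression, tissue-specificity calling, abundance ranking and co-expression.

The differential-expression engine is a self-contained two-sided exact test
on the negative-binomial model, conditioning on the pooled per-transcript sum
after library-size equalisation, with a common dispersion estimated by method
of moments across transcripts.  The decision rule is FDR <= 0.01 (inclusive)
and |log2 fold change| >= 1 (inclusive) by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import binom

from .io import CountMatrix

__all__ = [
    "ExpressionTable",
    "DeResult",
    "SpecificityCall",
    "compute_fpkm",
    "exact_nb_test",
    "bh_adjust",
    "equalize_library_sizes",
    "estimate_common_dispersion",
    "call_de",
    "call_specific",
    "top_abundant",
    "coexpression",
]


@dataclass
class ExpressionTable:
    """Counts plus derived FPKM and per-group mean FPKM."""

    counts: CountMatrix
    effective_lengths: dict[str, float]
    fpkm: pd.DataFrame  # transcript x sample
    group_means: pd.DataFrame  # transcript x group


@dataclass(frozen=True)
class DeResult:
    transcript_id: str
    group_a: str
    group_b: str
    log2_fold_change: float
    p_value: float
    fdr: float
    is_de: bool


@dataclass(frozen=True)
class SpecificityCall:
    transcript_id: str
    specific_in: str | None
    hi_threshold: float = 3.0
    lo_threshold: float = 1.0


def compute_fpkm(
    counts: CountMatrix, effective_lengths: Mapping[str, float]
) -> ExpressionTable:
    """FPKM[t, s] = counts[t, s] / ((L_t / 1e3) * (libsize_s / 1e6))."""
    lengths = np.array(
        [effective_lengths[t] if t in effective_lengths else np.nan for t in counts.transcript_ids]
    )
    if np.isnan(lengths).any():
        missing = [t for t in counts.transcript_ids if t not in effective_lengths]
        raise KeyError(f"missing effective lengths for: {missing[:5]}")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    libsizes = counts.library_sizes
    if (libsizes <= 0).any():
        zero = [s for s, n in zip(counts.sample_labels, libsizes) if n <= 0]
        raise ValueError(f"zero library size for samples: {zero}")
    fpkm_values = counts.counts / (lengths[:, None] / 1e3) / (libsizes[None, :] / 1e6)
    fpkm = pd.DataFrame(fpkm_values, index=counts.transcript_ids, columns=counts.sample_labels)
    group_means = pd.DataFrame(
        {g: fpkm[counts.samples_of_group(g)].mean(axis=1) for g in counts.groups}
    )
    return ExpressionTable(
        counts=counts,
        effective_lengths={t: float(effective_lengths[t]) for t in counts.transcript_ids},
        fpkm=fpkm,
        group_means=group_means,
    )


def exact_nb_test(
    counts_a: Sequence[float], counts_b: Sequence[float], dispersion: float = 0.0
) -> float:
    """Two-sided exact test for a difference in negative-binomial means.

    Conditions on the pooled sum ``s``: under the null of equal means (with
    library sizes already equalised) the group-A sum given ``s`` follows a
    generalised hypergeometric law with size parameters ``n_a / dispersion``
    and ``n_b / dispersion``; ``dispersion = 0`` reduces to the conditional
    binomial (Poisson) test.  The p-value sums the probabilities of all
    outcomes no more likely than the observed one (minimum-likelihood rule).
    """
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    a = np.asarray(np.rint(counts_a), dtype=np.int64)
    b = np.asarray(np.rint(counts_b), dtype=np.int64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups need at least one replicate")
    y_a = int(a.sum())
    s = y_a + int(b.sum())
    if s == 0:
        return 1.0
    n_a, n_b = a.size, b.size
    y = np.arange(s + 1)
    if dispersion < 1e-12:
        logw = binom.logpmf(y, s, n_a / (n_a + n_b))
    else:
        r_a = n_a / dispersion
        r_b = n_b / dispersion
        logw = (
            gammaln(y + r_a)
            - gammaln(y + 1)
            + gammaln(s - y + r_b)
            - gammaln(s - y + 1)
        )
        logw -= logsumexp(logw)
    # sum all outcomes whose likelihood does not exceed the observed one
    tol = logw[y_a] + 1e-9
    p = float(np.exp(logsumexp(logw[logw <= tol])))
    return min(p, 1.0)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def equalize_library_sizes(counts: CountMatrix) -> CountMatrix:
    """Scale every sample to the geometric-mean library size, rounding to the
    nearest integer (exact conditional tests need integer counts)."""
    libsizes = counts.library_sizes
    if (libsizes <= 0).any():
        raise ValueError("cannot equalise zero library sizes")
    target = float(np.exp(np.mean(np.log(libsizes))))
    scaled = np.rint(counts.counts * (target / libsizes)[None, :])
    return CountMatrix(
        transcript_ids=counts.transcript_ids,
        sample_labels=counts.sample_labels,
        counts=scaled,
        group_of_sample=counts.group_of_sample,
    )


def estimate_common_dispersion(counts: CountMatrix) -> float:
    """Method-of-moments common dispersion across transcripts.

    Per transcript, within-group mean m and variance v give a moment estimate
    (v - m) / m^2; the common value is the median over transcripts with
    positive estimates (0 if none — Poisson-like data).
    """
    estimates = []
    groups = counts.groups
    cols = {g: [counts.sample_labels.index(s) for s in counts.samples_of_group(g)] for g in groups}
    for row in counts.counts:
        num = 0.0
        den = 0.0
        for g in groups:
            x = row[cols[g]]
            if x.size < 2:
                continue
            m = x.mean()
            if m <= 0:
                continue
            v = x.var(ddof=1)
            num += v - m
            den += m * m
        if den > 0:
            estimates.append(num / den)
    if not estimates:
        return 0.0
    positive = [e for e in estimates if e > 0]
    if not positive:
        return 0.0
    return float(np.median(positive))


def call_de(
    table: ExpressionTable,
    group_a: str,
    group_b: str,
    dispersion_mode: str | float = "auto",
    fc_min: float = 2.0,
    fdr_max: float = 0.01,
    pseudo_count: float = 1.0,
) -> list[DeResult]:
    """Per-transcript differential expression between two groups.

    ``dispersion_mode`` is ``"auto"`` (method-of-moments common dispersion)
    or a numeric dispersion.  log2 fold change uses equalised group-mean
    counts with ``pseudo_count`` added to each group mean; a transcript is DE
    iff ``fdr <= fdr_max`` and ``|log2FC| >= log2(fc_min)``.
    """
    counts = table.counts
    for g in (group_a, group_b):
        if g not in counts.groups:
            raise KeyError(f"unknown group {g!r}")
    eq = equalize_library_sizes(counts)
    if dispersion_mode == "auto":
        dispersion = estimate_common_dispersion(eq)
    else:
        dispersion = float(dispersion_mode)

    idx_a = [eq.sample_labels.index(s) for s in eq.samples_of_group(group_a)]
    idx_b = [eq.sample_labels.index(s) for s in eq.samples_of_group(group_b)]
    p_values = np.empty(len(eq.transcript_ids))
    log2fc = np.empty(len(eq.transcript_ids))
    for i, row in enumerate(eq.counts):
        a, b = row[idx_a], row[idx_b]
        p_values[i] = exact_nb_test(a, b, dispersion)
        log2fc[i] = np.log2((b.mean() + pseudo_count) / (a.mean() + pseudo_count))
    fdr = bh_adjust(p_values)
    lfc_min = np.log2(fc_min)
    return [
        DeResult(
            transcript_id=tid,
            group_a=group_a,
            group_b=group_b,
            log2_fold_change=float(log2fc[i]),
            p_value=float(p_values[i]),
            fdr=float(fdr[i]),
            is_de=bool(fdr[i] <= fdr_max and abs(log2fc[i]) >= lfc_min),
        )
        for i, tid in enumerate(eq.transcript_ids)
    ]


def call_de_union(
    table: ExpressionTable,
    dispersion_mode: str | float = "auto",
    fc_min: float = 2.0,
    fdr_max: float = 0.01,
) -> set[str]:
    """Union of DE calls over all pairwise group contrasts."""
    groups = table.counts.groups
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    de_ids: set[str] = set()
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for r in call_de(table, groups[i], groups[j], dispersion_mode, fc_min, fdr_max):
                if r.is_de:
                    de_ids.add(r.transcript_id)
    return de_ids


def call_specific(
    table: ExpressionTable, hi: float = 3.0, lo: float = 1.0
) -> list[SpecificityCall]:
    """Call transcripts specifically expressed in a single group: group-mean
    FPKM strictly above ``hi`` in one group and strictly below ``lo`` in
    every other group."""
    if hi < lo:
        raise ValueError("hi threshold must be >= lo threshold")
    groups = list(table.group_means.columns)
    if len(groups) < 2:
        raise ValueError("specificity calling needs at least two groups")
    calls: list[SpecificityCall] = []
    means = table.group_means
    for tid, row in means.iterrows():
        specific_in = None
        for g in groups:
            if row[g] > hi and all(row[h] < lo for h in groups if h != g):
                specific_in = g
                break
        calls.append(
            SpecificityCall(transcript_id=str(tid), specific_in=specific_in, hi_threshold=hi, lo_threshold=lo)
        )
    return calls


def top_abundant(table: ExpressionTable, group: str, n: int = 1000) -> list[str]:
    """Transcript ids ranked by descending group-mean FPKM (ties by id)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if group not in table.group_means.columns:
        raise KeyError(f"unknown group {group!r}")
    ranked = sorted(
        table.group_means.index, key=lambda tid: (-table.group_means.at[tid, group], tid)
    )
    return [str(t) for t in ranked[:n]]


def coexpression(
    table: ExpressionTable,
    seed_ids: Sequence[str],
    candidate_ids: Sequence[str],
    min_abs_r: float = 0.9,
) -> list[tuple[str, str, float]]:
    """Pearson correlation of log2(FPKM + 1) across all samples for every
    (seed, candidate) pair; pairs with |r| >= ``min_abs_r`` returned sorted
    by |r| descending.  Zero-variance transcripts are skipped with a warning.
    """
    fpkm = table.fpkm
    for tid in list(seed_ids) + list(candidate_ids):
        if tid not in fpkm.index:
            raise KeyError(f"unknown transcript {tid!r}")
    if fpkm.shape[1] < 3:
        raise ValueError("correlation needs at least 3 samples")
    logx = np.log2(fpkm + 1.0)

    def usable(tid: str) -> bool:
        if np.std(logx.loc[tid].values) == 0:
            warnings.warn(f"transcript {tid!r} has zero variance; skipped", stacklevel=2)
            return False
        return True

    seeds = [t for t in seed_ids if usable(t)]
    candidates = [t for t in candidate_ids if usable(t)]
    pairs: list[tuple[str, str, float]] = []
    for s in seeds:
        xs = logx.loc[s].values
        for c in candidates:
            if c == s:
                continue
            r = float(np.corrcoef(xs, logx.loc[c].values)[0, 1])
            if abs(r) >= min_abs_r:
                pairs.append((s, c, r))
    pairs.sort(key=lambda p: (-abs(p[2]), p[0], p[1]))
    return pairs
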