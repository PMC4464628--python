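"""KO-table driven grouping of pathway genes with copy-number counts."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "PathwayGeneGroup",
    "group_pathway_genes",
    "read_ko_table",
    "load_pathway_definition",
]


@dataclass(frozen=True)
class PathwayGeneGroup:
    enzyme_label: str
    ko_id: str
    member_transcripts: tuple[str, ...]

    @property
    def copy_count(self) -> int:
        return len(self.member_transcripts)


def read_ko_table(path) -> list[tuple[str, str, str]]:
    """Read a (transcript_id, KO, pathway) TSV; header optional."""
    rows: list[tuple[str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in {"transcript_id", "id"}:
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected >= 2 columns")
            rows.append((fields[0], fields[1], fields[2] if len(fields) > 2 else ""))
    return rows


def load_pathway_definition(path) -> dict[str, list[str]]:
    """Load an enzyme_label -> [KO ids] mapping from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"pathway definition in {path} must be a mapping")
    out: dict[str, list[str]] = {}
    for label, kos in data.items():
        if isinstance(kos, str):
            kos = [kos]
        out[str(label)] = [str(k) for k in kos]
    return out


def group_pathway_genes(
    ko_table: Iterable[tuple[str, str, str]] | Mapping[str, str],
    pathway_definition: Mapping[str, Sequence[str]],
) -> list[PathwayGeneGroup]:
    """One group per (enzyme label, KO id) with the distinct transcripts
    assigned that KO; transcripts matching no pathway KO are ignored."""
    for label, kos in pathway_definition.items():
        if not kos:
            raise ValueError(f"enzyme label {label!r} has no KO ids")
    if isinstance(ko_table, Mapping):
        assignments = [(t, k, "") for t, k in ko_table.items()]
    else:
        assignments = list(ko_table)
    by_ko: dict[str, list[str]] = {}
    for transcript_id, ko, _pathway in assignments:
        members = by_ko.setdefault(ko, [])
        if transcript_id not in members:
            members.append(transcript_id)
    groups: list[PathwayGeneGroup] = []
    for label, kos in pathway_definition.items():
        for ko in kos:
            members = tuple(sorted(by_ko.get(ko, [])))
            groups.append(PathwayGeneGroup(enzyme_label=label, ko_id=ko, member_transcripts=members))
    return groups


def write_groups_tsv(groups: Iterable[PathwayGeneGroup], path) -> None:
    with open(path, "w") as fh:
        fh.write("enzyme_label\tko_id\tcopy_count\tmember_transcripts\n")
        for g in groups:
            fh.write(f"{g.enzyme_label}\t{g.ko_id}\t{g.copy_count}\t{','.join(g.member_transcripts)}\n")
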