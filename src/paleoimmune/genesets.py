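"""Pathway collections: membership, immune labels, signed regulator subsets.

Pathways are stored as plain gene-id lists.  A *signed* pathway additionally
partitions (a subset of) its genes into positive and negative regulators of
the underlying process, which is what the direction-of-activity inference
consumes.  On disk the formats are the field's usual plain-text ones: GMT
for membership (positive/negative regulator subsets as paired ``.pos.gmt`` /
``.neg.gmt`` files) and a two-column TSV for immune labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class Pathway:
    id: str
    genes: list[str]
    immune: bool = False
    positive: list[str] = field(default_factory=list)
    negative: list[str] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError(f"duplicate gene ids in pathway {self.id}")
        if set(self.positive) & set(self.negative):
            raise ValueError(f"overlapping signed subsets in pathway {self.id}")

    @property
    def signed(self) -> bool:
        return bool(self.positive or self.negative)

    def regulator_signs(self) -> dict[str, int]:
        """Gene -> +1 (positive regulator) / -1 (negative regulator)."""
        signs = {g: +1 for g in self.positive}
        signs.update({g: -1 for g in self.negative})
        return signs


@dataclass
class GeneSetCollection:
    pathways: list[Pathway]

    def __iter__(self):
        return iter(self.pathways)

    def __len__(self) -> int:
        return len(self.pathways)

    def __getitem__(self, pathway_id: str) -> Pathway:
        for p in self.pathways:
            if p.id == pathway_id:
                return p
        raise KeyError(pathway_id)

    @property
    def ids(self) -> list[str]:
        return [p.id for p in self.pathways]

    def immune_flags(self) -> dict[str, bool]:
        return {p.id: p.immune for p in self.pathways}


def write_gmt(pathways: list[Pathway] | GeneSetCollection, path: str | Path,
              description: str = "synthetic") -> None:
    with open(path, "w") as fh:
        for p in pathways:
            fh.write("\t".join([p.id, description, *p.genes]) + "\n")


def read_gmt(path: str | Path, source: str | None = None) -> GeneSetCollection:
    pathways = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            pathways.append(
                Pathway(id=fields[0], genes=list(fields[2:]),
                        source=source or str(path))
            )
    return GeneSetCollection(pathways)


def write_signed_gmt(collection: GeneSetCollection, prefix: str | Path) -> None:
    """Write ``<prefix>.pos.gmt`` / ``<prefix>.neg.gmt`` for signed pathways."""
    signed = [p for p in collection if p.signed]
    pos = [Pathway(p.id, list(p.positive), p.immune) for p in signed if p.positive]
    neg = [Pathway(p.id, list(p.negative), p.immune) for p in signed if p.negative]
    write_gmt(pos, f"{prefix}.pos.gmt", description="positive_regulators")
    write_gmt(neg, f"{prefix}.neg.gmt", description="negative_regulators")


def read_signed_gmt(prefix: str | Path,
                    immune_labels: dict[str, bool] | None = None) -> GeneSetCollection:
    pos = read_gmt(f"{prefix}.pos.gmt")
    neg = read_gmt(f"{prefix}.neg.gmt")
    ids = list(dict.fromkeys(pos.ids + neg.ids))
    out = []
    for pid in ids:
        pgenes = pos[pid].genes if pid in pos.ids else []
        ngenes = neg[pid].genes if pid in neg.ids else []
        out.append(Pathway(
            id=pid, genes=pgenes + ngenes,
            immune=bool(immune_labels.get(pid, False)) if immune_labels else False,
            positive=pgenes, negative=ngenes,
        ))
    return GeneSetCollection(out)


def write_immune_labels(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("pathway\timmune\n")
        for p in collection:
            fh.write(f"{p.id}\t{int(p.immune)}\n")


def read_immune_labels(path: str | Path) -> dict[str, bool]:
    labels: dict[str, bool] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("pathway"):
            raise ValueError("immune label file must have a 'pathway\\timmune' header")
        for line in fh:
            pid, flag = line.rstrip("\n").split("\t")
            labels[pid] = bool(int(flag))
    return labels
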