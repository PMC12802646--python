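"""Senescence gene sets: ingestion, consensus building, and overlap statistics.

Published senescence-associated gene sets (SnGs) disagree heavily: sizes span
two orders of magnitude and pairwise Jaccard indices are typically below 0.2.
A consensus panel — genes reported by at least five of nine sets — is far more
robust to the inclusion bias of any single list and is the default input panel
for the autoencoder model.  This module provides the :class:`GeneSet` /
:class:`GeneSetCollection` containers, the literature-database retention rule,
the consensus builder, and the overlap statistics used to quantify
inter-set discrepancy.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "SeneQuestRecord",
    "filter_senequest",
    "consensus",
    "jaccard",
    "membership_histogram",
    "read_gmt",
    "write_gmt",
    "read_direction_tsv",
    "write_direction_tsv",
    "load_packaged_sngs",
    "load_core_panel",
]

VALID_DIRECTIONS = ("induces", "inhibits", "unknown")


def _clean(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class GeneSet:
    """A named gene set with optional per-gene regulatory direction.

    Gene symbols are upper-cased and whitespace-trimmed on construction so
    that sets from different sources match on symbol.  ``direction``, when
    present, maps every gene to one of ``induces`` / ``inhibits`` /
    ``unknown`` (whether the gene promotes or suppresses senescence).
    """

    name: str
    genes: list[str]
    direction: dict[str, str] | None = None

    def __post_init__(self) -> None:
        cleaned: list[str] = []
        seen: set[str] = set()
        for g in self.genes:
            g = _clean(g)
            if g and g not in seen:
                seen.add(g)
                cleaned.append(g)
        self.genes = cleaned
        if self.direction is not None:
            d = {_clean(g): v for g, v in self.direction.items()}
            for g, v in d.items():
                if v not in VALID_DIRECTIONS:
                    raise ValueError(f"invalid direction {v!r} for gene {g}")
            missing = [g for g in self.genes if g not in d]
            if missing:
                d.update({g: "unknown" for g in missing})
            self.direction = d

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, symbol: str) -> bool:
        return _clean(symbol) in set(self.genes)

    def as_set(self) -> set[str]:
        return set(self.genes)


@dataclass
class GeneSetCollection:
    """A list of gene sets plus the derived gene -> membership-count map."""

    sets: list[GeneSet]
    membership: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        self.membership = dict(
            Counter(g for s in self.sets for g in s.as_set())
        )

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class SeneQuestRecord:
    """One gene's evidence summary from a senescence literature database.

    ``n_publications`` counts papers reporting the gene; ``direction_agreement``
    is the fraction of those agreeing with the majority direction;
    ``majority_direction`` is that direction.
    """

    gene: str
    n_publications: int
    direction_agreement: float
    majority_direction: str = "unknown"

    def __post_init__(self) -> None:
        if not 0.0 <= self.direction_agreement <= 1.0:
            raise ValueError(
                f"direction_agreement must lie in [0, 1], got "
                f"{self.direction_agreement} for gene {self.gene}"
            )
        if self.n_publications < 0:
            raise ValueError("n_publications must be non-negative")


def filter_senequest(
    records: Sequence[SeneQuestRecord],
    min_publications: int = 15,
    min_pubs_with_agreement: int = 4,
    min_agreement: float = 0.70,
    name: str = "senequest_filtered",
) -> GeneSet:
    """Apply the literature-database retention rule.

    A gene is retained if it was reported by at least 15 publications, or by
    at least four publications with at least 70% agreement on whether it
    induces or inhibits senescence.  The retained gene carries its majority
    direction.
    """
    if not records:
        raise ValueError("records must be non-empty")
    genes: list[str] = []
    direction: dict[str, str] = {}
    for r in records:
        keep = r.n_publications >= min_publications or (
            r.n_publications >= min_pubs_with_agreement
            and r.direction_agreement >= min_agreement
        )
        if keep:
            genes.append(r.gene)
            direction[_clean(r.gene)] = r.majority_direction
    return GeneSet(name=name, genes=genes, direction=direction)


def _majority_direction(gene: str, sets: Iterable[GeneSet]) -> str:
    votes = Counter()
    for s in sets:
        if s.direction is None:
            continue
        d = s.direction.get(gene)
        if d in ("induces", "inhibits"):
            votes[d] += 1
    if not votes:
        return "unknown"
    top = votes.most_common()
    if len(top) == 2 and top[0][1] == top[1][1]:
        return "unknown"  # 50/50 conflict across sources
    return top[0][0]


def consensus(
    collection: GeneSetCollection,
    min_sets: int = 5,
    name: str = "consensus",
) -> GeneSet:
    """Genes present in at least ``min_sets`` member sets, alphabetically.

    Each consensus gene carries the majority direction across the member
    sets that annotate one (``unknown`` on an exact tie).  If ``min_sets``
    exceeds the number of sets the result is empty, with a warning.
    """
    if min_sets < 1:
        raise ValueError("min_sets must be >= 1")
    if min_sets > len(collection.sets):
        warnings.warn(
            f"min_sets={min_sets} exceeds the number of sets "
            f"({len(collection.sets)}); consensus is empty",
            stacklevel=2,
        )
    genes = sorted(
        g for g, n in collection.membership.items() if n >= min_sets
    )
    direction = {g: _majority_direction(g, collection.sets) for g in genes}
    return GeneSet(name=name, genes=genes, direction=direction)


def jaccard(a: GeneSet, b: GeneSet) -> float:
    """Jaccard overlap |a∩b| / |a∪b|; defined as 0.0 when both sets are empty."""
    sa, sb = a.as_set(), b.as_set()
    union = sa | sb
    if not union:
        return 0.0
    return len(sa & sb) / len(union)


def membership_histogram(collection: GeneSetCollection) -> dict[int, int]:
    """Histogram: number of member sets -> number of genes with that count."""
    if not collection.sets:
        raise ValueError("collection must be non-empty")
    return dict(Counter(collection.membership.values()))


# ---------------------------------------------------------------------------
# File formats: GMT (name, description, genes...) and two-column TSV

def read_gmt(path: str | Path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed GMT line in {path}: {line[:60]!r}")
            sets.append(GeneSet(name=fields[0], genes=fields[2:]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path,
              description: str = "") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description] + s.genes) + "\n")


def read_direction_tsv(path: str | Path, name: str | None = None) -> GeneSet:
    """Read a two-column (gene, direction) TSV; a lone gene column is allowed."""
    genes: list[str] = []
    direction: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        has_direction = len(header) > 1
        if _clean(header[0]) != "GENE":  # headerless file: first row is data
            genes.append(header[0])
            if has_direction:
                direction[_clean(header[0])] = header[1]
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields[0].strip():
                continue
            genes.append(fields[0])
            if has_direction and len(fields) > 1:
                direction[_clean(fields[0])] = fields[1]
    return GeneSet(
        name=name or Path(path).stem,
        genes=genes,
        direction=direction if direction else None,
    )


def write_direction_tsv(gene_set: GeneSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\tdirection\n")
        for g in gene_set.genes:
            d = (gene_set.direction or {}).get(g, "unknown")
            fh.write(f"{g}\t{d}\n")


# ---------------------------------------------------------------------------
# Packaged synthetic fixtures

def _data_dir() -> Path:
    return Path(resources.files("snscore") / "data")


def load_packaged_sngs() -> GeneSetCollection:
    """Load the nine packaged senescence gene sets.

    These are synthetic stand-ins that mimic the size spread and overlap
    structure of the published senescence-gene-set literature; two of them
    carry direction annotations.
    """
    d = _data_dir() / "synthetic_sngs"
    sets = []
    for gmt in sorted(d.glob("sng*.synthetic.gmt")):
        (s,) = read_gmt(gmt)
        sidecar = gmt.with_name(gmt.name.replace(".gmt", ".directions.tsv"))
        if sidecar.exists():
            ann = read_direction_tsv(sidecar)
            s = GeneSet(name=s.name, genes=s.genes, direction=ann.direction)
        sets.append(s)
    return GeneSetCollection(sets=sets)


def load_core_panel() -> GeneSet:
    """The packaged 39-gene consensus senescence panel (synthetic fixture)."""
    gs = read_direction_tsv(
        _data_dir() / "synthetic_sngs" / "core_panel.synthetic.tsv",
        name="core_panel",
    )
    return gs
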