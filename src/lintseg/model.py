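"""Domain types for the cotton lint% dissection toolkit.

The genetic system modelled here is the tetraploid cotton lint-percentage
(lint%) architecture: up to four unlinked causal loci (the At/Dt homoeologs
of *MYB25-like* and *HD1*), each segregating a functional and a
loss-of-function allele.  Loss-of-function alleles carry additive lint%
penalties with optional dominance (separate heterozygote penalty) and
epistatic masking (a penalty expressed only in a permissive genotype at a
second locus).  Seed-fuzz phenotype follows a two-locus rule: fuzzless iff
the individual carries >=1 loss-of-function allele at the dominant-fuzzless
locus or is homozygous loss-of-function at the recessive-fuzzless locus.

Haplotypes are stored as dense allele vectors over a marker map, one pair of
vectors per chromosome, with allele values encoding parental origin
(0 = parent A, 1 = parent B).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

ALLELE_A = 0
ALLELE_B = 1

#: canonical ids of the four default causal loci
MYB25_AT = "MYB25like_At"
MYB25_DT = "MYB25like_Dt"
HD1_AT = "HD1_At"
HD1_DT = "HD1_Dt"


@dataclass
class GenomeMap:
    """Marker map over a set of chromosomes.

    Parameters
    ----------
    chromosomes
        ``(name, length_bp)`` pairs.
    marker_positions
        Per chromosome, strictly increasing 1-based bp positions.
    recomb_rate_cM_per_Mbp
        Single genome-wide recombination rate; map distance between adjacent
        markers is ``rate * delta_bp / 1e6`` centimorgans, converted to
        recombination fractions with the Haldane map function (no
        interference).
    """

    chromosomes: Sequence[tuple[str, int]]
    marker_positions: Mapping[str, np.ndarray]
    recomb_rate_cM_per_Mbp: float = 1.0

    def __post_init__(self) -> None:
        if self.recomb_rate_cM_per_Mbp < 0:
            raise ValueError("recombination rate must be non-negative")
        self.chromosomes = [(str(c), int(l)) for c, l in self.chromosomes]
        lengths = dict(self.chromosomes)
        positions: dict[str, np.ndarray] = {}
        for chrom, pos in self.marker_positions.items():
            if chrom not in lengths:
                raise ValueError(f"marker positions given for undeclared chromosome {chrom!r}")
            arr = np.asarray(pos, dtype=np.int64)
            if arr.ndim != 1 or arr.size == 0:
                raise ValueError(f"chromosome {chrom!r} needs a 1-d, non-empty marker array")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"marker positions on {chrom!r} must be strictly increasing")
            if arr[0] < 1 or arr[-1] > lengths[chrom]:
                raise ValueError(f"marker positions on {chrom!r} outside [1, {lengths[chrom]}]")
            positions[chrom] = arr
        self.marker_positions = positions

    @property
    def chrom_names(self) -> list[str]:
        return [c for c, _ in self.chromosomes]

    def length(self, chrom: str) -> int:
        for c, l in self.chromosomes:
            if c == chrom:
                return l
        raise KeyError(chrom)

    def positions(self, chrom: str) -> np.ndarray:
        return self.marker_positions[chrom]

    def marker_index(self, chrom: str, position_bp: int) -> int:
        """Index of an exact marker position; raises if absent."""
        pos = self.marker_positions[chrom]
        i = int(np.searchsorted(pos, position_bp))
        if i >= pos.size or pos[i] != position_bp:
            raise KeyError(f"position {position_bp} is not a marker on {chrom}")
        return i

    @classmethod
    def default(
        cls,
        chrom_names: Sequence[str] = ("Chr-A12", "Chr-D12", "Chr-A06", "Chr-D06"),
        length_bp: int = 100_000_000,
        marker_spacing_bp: int = 100_000,
        recomb_rate_cM_per_Mbp: float = 1.0,
    ) -> "GenomeMap":
        """Desk-scale stand-in genome: 4 chromosomes x 100 Mbp, markers every 100 kb."""
        markers = np.arange(marker_spacing_bp, length_bp + 1, marker_spacing_bp, dtype=np.int64)
        return cls(
            chromosomes=[(c, length_bp) for c in chrom_names],
            marker_positions={c: markers.copy() for c in chrom_names},
            recomb_rate_cM_per_Mbp=recomb_rate_cM_per_Mbp,
        )


@dataclass(frozen=True)
class CausalLocus:
    """A causal locus with a loss-of-function allele carried by one (or both) parents.

    ``dysfunctional`` names which parent's allele is loss-of-function:
    ``"A"``, ``"B"``, ``"both"`` (the locus is fixed dysfunctional in the
    cross) or ``None`` (fixed functional).
    """

    id: str
    chromosome: str
    position_bp: int
    allele_labels: tuple[str, str] = ("A", "B")
    dysfunctional: str | None = "A"

    def __post_init__(self) -> None:
        if self.dysfunctional not in ("A", "B", "both", None):
            raise ValueError("dysfunctional must be 'A', 'B', 'both' or None")

    def validate_on(self, gmap: GenomeMap) -> None:
        if self.chromosome not in gmap.chrom_names:
            raise ValueError(f"locus {self.id} on undeclared chromosome {self.chromosome}")
        if not (1 <= self.position_bp <= gmap.length(self.chromosome)):
            raise ValueError(f"locus {self.id} position outside chromosome {self.chromosome}")
        if gmap.positions(self.chromosome).size < 2:
            raise ValueError(f"chromosome {self.chromosome} carrying locus {self.id} has <2 markers")
        gmap.marker_index(self.chromosome, self.position_bp)


@dataclass
class EffectModel:
    """Genotype -> expected lint% map with additive penalties, masking and a fuzz rule.

    The expected lint% of a joint genotype is ``baseline_lint_pct`` minus the
    per-locus penalty for that locus's loss-of-function dosage (0, 1 or 2
    copies), clipped at 0 (lint% of exactly 0 is the fiberless class).  A
    masking rule ``(masked, masking, required_dosage)`` suspends the masked
    locus's penalty unless the masking locus has the stated dosage.
    An explicit joint-genotype table may override the additive combination.
    """

    baseline_lint_pct: float
    penalties: Mapping[str, tuple[float, float, float]] = field(default_factory=dict)
    masking_rules: Sequence[tuple[str, str, int]] = field(default_factory=list)
    explicit_classes: Mapping[tuple[int, ...], float] | None = None
    locus_order: Sequence[str] | None = None
    noise_sd: float = 2.0
    fuzz_dominant: str | None = None
    fuzz_recessive: str | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.explicit_classes is not None and self.locus_order is None:
            raise ValueError("explicit_classes requires locus_order")
        for lid, trip in self.penalties.items():
            if len(trip) != 3:
                raise ValueError(f"penalty triplet for {lid} must have 3 entries (dosage 0/1/2)")

    def _masked_out(self, locus_id: str, dosages: Mapping[str, int]) -> bool:
        for masked, masking, required in self.masking_rules:
            if masked == locus_id:
                if masking not in dosages:
                    raise KeyError(f"masking locus {masking} has no genotype")
                if dosages[masking] != required:
                    return True
        return False

    def expected_lint(self, dosages: Mapping[str, int]) -> float:
        """Expected (noise-free) lint% for a joint loss-of-function dosage vector."""
        if self.explicit_classes is not None:
            key = tuple(int(dosages[l]) for l in self.locus_order)  # type: ignore[union-attr]
            return max(0.0, float(self.explicit_classes[key]))
        total = self.baseline_lint_pct
        for lid, trip in self.penalties.items():
            if lid not in dosages:
                raise KeyError(f"genotype at causal locus {lid} missing")
            if not self._masked_out(lid, dosages):
                total -= trip[int(dosages[lid])]
        return max(0.0, total)

    def is_fuzzless(self, dosages: Mapping[str, int]) -> bool:
        dom = self.fuzz_dominant is not None and dosages.get(self.fuzz_dominant, 0) >= 1
        rec = self.fuzz_recessive is not None and dosages.get(self.fuzz_recessive, 0) == 2
        return bool(dom or rec)


@dataclass
class Individual:
    """One plant: a pair of haplotype vectors per chromosome plus phenotypes.

    ``haplotypes[chrom]`` is a ``(2, n_markers)`` uint8 array aligned with
    ``GenomeMap.positions(chrom)``; allele values are parental origins.
    """

    haplotypes: dict[str, np.ndarray]
    lint_pct: float | None = None
    fuzzless: bool | None = None
    pedigree_tag: str = ""

    @property
    def fiberless(self) -> bool:
        return self.lint_pct == 0.0

    def alleles_at(self, gmap: GenomeMap, chrom: str, position_bp: int) -> np.ndarray:
        idx = gmap.marker_index(chrom, position_bp)
        return self.haplotypes[chrom][:, idx]

    def dosage(self, locus: CausalLocus, gmap: GenomeMap) -> int:
        """Number of loss-of-function alleles (0/1/2) at a causal locus."""
        if locus.dysfunctional == "both":
            return 2
        if locus.dysfunctional is None:
            return 0
        target = ALLELE_A if locus.dysfunctional == "A" else ALLELE_B
        try:
            alleles = self.alleles_at(gmap, locus.chromosome, locus.position_bp)
        except KeyError as exc:
            raise KeyError(f"genotype at causal locus {locus.id} missing") from exc
        return int(np.sum(alleles == target))


def founder(gmap: GenomeMap, origin: int, tag: str = "") -> Individual:
    """Fully inbred founder line: both haplotypes carry a single parental origin."""
    if origin not in (ALLELE_A, ALLELE_B):
        raise ValueError("origin must be 0 (parent A) or 1 (parent B)")
    haps = {
        c: np.full((2, gmap.positions(c).size), origin, dtype=np.uint8)
        for c in gmap.chrom_names
    }
    return Individual(haplotypes=haps, pedigree_tag=tag)


@dataclass
class Population:
    """A cross generation sharing one genome map, causal loci and effect model."""

    individuals: list[Individual]
    cross_type: str
    parents: tuple[str, str]
    seed: int
    gmap: GenomeMap
    loci: Sequence[CausalLocus]
    model: EffectModel

    def __post_init__(self) -> None:
        if len(self.individuals) == 0:
            raise ValueError("population must contain at least one individual")

    def __len__(self) -> int:
        return len(self.individuals)

    def lint_values(self) -> np.ndarray:
        return np.array([i.lint_pct for i in self.individuals], dtype=float)

    def dosage_matrix(self) -> dict[str, np.ndarray]:
        """Per-locus loss-of-function dosage vector across the population."""
        return {
            l.id: np.array([ind.dosage(l, self.gmap) for ind in self.individuals], dtype=np.int8)
            for l in self.loci
        }

    def to_dataframe(self):
        import pandas as pd

        rows = {
            "id": [i.pedigree_tag for i in self.individuals],
            "cross": [self.cross_type] * len(self.individuals),
        }
        rows.update({lid: d for lid, d in self.dosage_matrix().items()})
        rows["lint_pct"] = self.lint_values()
        rows["fuzzless"] = [int(bool(i.fuzzless)) for i in self.individuals]
        return pd.DataFrame(rows)
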