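"""Shared domain types for the kinship / IBD analysis pipeline.

The types here mirror the tabular records the pipeline exchanges: individual
metadata as found in cemetery supplementary tables, IBD segments and per-pair
relatedness summaries, and radiocarbon calibration inputs.  Validation is
performed at construction so that every reader is total on its dialect and
rejects invariant-violating rows with a named error.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

SEXES = ("male", "female", "unknown")
AGE_CLASSES = ("adult", "subadult", "unknown")
PHASES = ("early", "middle", "late", "unknown")
DEGREES = ("identical", "parent_child", "sibling", "first_ambiguous",
           "second", "third", "unrelated")
IBD_STATES = ("IBD1", "IBD2")

ADULT_AGE_YEARS = 18  # adulthood threshold (years), lower bound of youngest parents


class FormatError(ValueError):
    """A file does not conform to its documented dialect."""


class ValidationError(ValueError):
    """A well-formed record violates a domain invariant."""


class SimulationError(RuntimeError):
    """A simulation constraint could not be satisfied."""


@dataclass
class Individual:
    """Metadata record for one buried individual."""

    id: str
    site: str
    sex: str = "unknown"
    age_class: str = "unknown"
    age_range_years: Optional[tuple[int, int]] = None
    phase: str = "unknown"
    y_haplogroup: Optional[str] = None
    mt_haplogroup: Optional[str] = None
    snp_count: Optional[int] = None
    grave_xy: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.sex not in SEXES:
            raise ValidationError(f"individual {self.id}: unknown sex {self.sex!r}")
        if self.age_class not in AGE_CLASSES:
            raise ValidationError(
                f"individual {self.id}: unknown age class {self.age_class!r}")
        if self.phase not in PHASES:
            raise ValidationError(f"individual {self.id}: unknown phase {self.phase!r}")
        if self.sex == "female" and self.y_haplogroup:
            raise ValidationError(
                f"individual {self.id}: Y haplogroup present for sex=female")
        if self.age_range_years is not None:
            lo, hi = self.age_range_years
            if lo > hi:
                raise ValidationError(
                    f"individual {self.id}: age range {lo}-{hi} inverted")
            if self.age_class == "adult" and lo < ADULT_AGE_YEARS:
                raise ValidationError(
                    f"individual {self.id}: adult with age minimum {lo} < "
                    f"{ADULT_AGE_YEARS}")
            if self.age_class == "subadult" and lo >= ADULT_AGE_YEARS:
                raise ValidationError(
                    f"individual {self.id}: subadult with age minimum {lo} >= "
                    f"{ADULT_AGE_YEARS}")
        if self.snp_count is not None and self.snp_count < 0:
            raise ValidationError(f"individual {self.id}: negative SNP count")

    @property
    def is_adult(self) -> bool:
        if self.age_class == "adult":
            return True
        if self.age_range_years is not None:
            return self.age_range_years[0] >= ADULT_AGE_YEARS
        return False


@dataclass(frozen=True)
class GeneticMap:
    """Ordered autosomal map: chromosome names and sex-averaged lengths in cM."""

    chromosomes: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValidationError("genetic map has no chromosomes")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValidationError(f"chromosome {name}: nonpositive length")
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate chromosome names in map")

    @property
    def total_cM(self) -> float:
        return float(sum(length for _, length in self.chromosomes))

    def length_of(self, chrom: str) -> float:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.chromosomes]


# Sex-averaged autosomal lengths (cM), chr1-22; total ~3,540 cM.
_DEFAULT_LENGTHS_CM = (
    286.28, 268.84, 223.36, 214.55, 204.09, 192.04, 187.22, 168.00,
    166.36, 181.14, 158.22, 174.68, 125.93, 120.20, 141.86, 134.04,
    128.49, 117.91, 107.87, 108.27, 62.79, 74.11,
)

DEFAULT_MAP = GeneticMap(
    tuple((f"chr{i + 1}", length) for i, length in enumerate(_DEFAULT_LENGTHS_CM)))


@dataclass(frozen=True)
class IBDSegment:
    """A genetic-map interval shared between two haplotype sets, [start, end) in cM."""

    chrom: str
    start_cM: float
    end_cM: float
    n_snps: Optional[int] = None
    state: str = "IBD1"

    def __post_init__(self) -> None:
        if self.start_cM >= self.end_cM:
            raise FormatError(
                f"segment on {self.chrom}: start {self.start_cM} >= end {self.end_cM}")
        if self.start_cM < 0:
            raise ValidationError(f"segment on {self.chrom}: negative start")
        if self.state not in IBD_STATES:
            raise ValidationError(f"segment on {self.chrom}: state {self.state!r}")

    @property
    def length_cM(self) -> float:
        return self.end_cM - self.start_cM

    @property
    def snp_density(self) -> Optional[float]:
        if self.n_snps is None:
            return None
        return self.n_snps / self.length_cM

    def within(self, gmap: GeneticMap) -> bool:
        try:
            return self.end_cM <= gmap.length_of(self.chrom) + 1e-9
        except KeyError:
            return False


@dataclass
class PairRelatedness:
    """Per-pair IBD summary with (optionally) the underlying segments."""

    id_a: str
    id_b: str
    segments: list[IBDSegment] = field(default_factory=list)
    total_ibd1_cM: float = 0.0
    total_ibd2_cM: float = 0.0
    n_segments: int = 0
    max_ibd_cM: float = 0.0
    kinship: float = 0.0
    degree: str = "unrelated"
    subtype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.id_a == self.id_b:
            raise ValidationError(f"pair with identical ids {self.id_a}")
        # canonical unordered key
        if self.id_b < self.id_a:
            self.id_a, self.id_b = self.id_b, self.id_a

    @property
    def key(self) -> tuple[str, str]:
        return (self.id_a, self.id_b)


@dataclass
class CalibrationCurve:
    """Radiocarbon calibration curve: cal BP vs conventional 14C age, with 1-sigma."""

    cal_bp: np.ndarray
    c14_age_bp: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.cal_bp = np.asarray(self.cal_bp, dtype=float)
        self.c14_age_bp = np.asarray(self.c14_age_bp, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.cal_bp.size < 2:
            raise FormatError("calibration curve needs at least 2 rows")
        order = np.argsort(self.cal_bp)
        self.cal_bp = self.cal_bp[order]
        self.c14_age_bp = self.c14_age_bp[order]
        self.sigma = self.sigma[order]
        if np.any(np.diff(self.cal_bp) <= 0):
            raise FormatError("calibration curve has duplicated cal BP knots")
        if np.any(self.sigma <= 0):
            raise FormatError("calibration curve has nonpositive sigma")

    def mean_at(self, cal_bp: np.ndarray | float) -> np.ndarray:
        return np.interp(cal_bp, self.cal_bp, self.c14_age_bp)

    def sigma_at(self, cal_bp: np.ndarray | float) -> np.ndarray:
        return np.interp(cal_bp, self.cal_bp, self.sigma)

    def covers(self, cal_bp: np.ndarray) -> bool:
        cal_bp = np.asarray(cal_bp, dtype=float)
        return bool(cal_bp.min() >= self.cal_bp[0] and cal_bp.max() <= self.cal_bp[-1])


@dataclass(frozen=True)
class RadiocarbonDate:
    individual_id: str
    c14_age_BP: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValidationError(
                f"date for {self.individual_id}: nonpositive sigma")


def canonical_pair(id_a: str, id_b: str) -> tuple[str, str]:
    """Order-independent key for an unordered pair of individual ids."""
    return (id_a, id_b) if id_a <= id_b else (id_b, id_a)


def merge_pair_segments(
    pairs: dict[tuple[str, str], list[IBDSegment]],
) -> dict[tuple[str, str], list[IBDSegment]]:
    """Sort each pair's segments by (chrom, start) for deterministic output."""
    out = {}
    for key in sorted(pairs):
        out[key] = sorted(pairs[key], key=lambda s: (s.chrom, s.start_cM, s.end_cM))
    return out


def as_sequence(values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sequence of values")
    return arr
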