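"""Core domain types for inbred-panel association mapping.

The panel is a collection of fully homozygous lines, so genotype at a
biallelic marker is a single 0/1 call per line (0 = homozygous reference,
1 = homozygous alternate); heterozygous states do not exist in the model
and are treated as missing on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The two rearing diets: ad libitum (5 % yeast) and dietary restriction
#: (0.5 % yeast).  Diet is coded AL = 0, DR = 1 throughout.
DIETS = ("AL", "DR")


@dataclass
class Marker:
    """A biallelic marker.

    ``pos`` is 1-based (VCF convention); all internal interval arithmetic
    converts to 0-based half-open.  ``maf`` is the minor allele frequency
    computed over non-missing calls only, so it always lies in [0, 0.5].
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str = "A"
    alt_allele: str = "T"
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"marker {self.id}: pos must be >= 1, got {self.pos}")


@dataclass
class GeneModel:
    """A gene interval, stored 0-based half-open.

    ``is_disease_homolog`` marks genes whose human homolog is a known
    disease gene; it drives the optional homolog-subset scans.
    """

    id: str
    chrom: str
    start: int
    end: int
    is_disease_homolog: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"gene {self.id}: start must be < end")

    @property
    def length(self) -> int:
        return self.end - self.start


class GenotypePanel:
    """Line x marker matrix of homozygous calls.

    ``calls`` is a float array of shape (n_lines, n_markers) with values
    0.0, 1.0 or NaN (missing).  Column order matches ``markers``, row
    order matches ``lines``.
    """

    def __init__(self, lines: list[str], markers: list[Marker], calls: np.ndarray):
        calls = np.asarray(calls, dtype=float)
        if calls.shape != (len(lines), len(markers)):
            raise ValueError(
                f"calls shape {calls.shape} does not match "
                f"{len(lines)} lines x {len(markers)} markers"
            )
        valid = np.isnan(calls) | (calls == 0.0) | (calls == 1.0)
        if not valid.all():
            raise ValueError("calls must be 0, 1 or NaN (homozygous panel)")
        if calls.shape[1] and np.isnan(calls).all(axis=0).any():
            raise ValueError("every marker needs at least one non-missing call")
        self.lines = list(lines)
        self.markers = list(markers)
        self.calls = calls
        self._refresh_maf()

    def _refresh_maf(self) -> None:
        if not self.markers:
            return
        with np.errstate(invalid="ignore"):
            freq = np.nanmean(self.calls, axis=0)
        maf = np.minimum(freq, 1.0 - freq)
        for m, f in zip(self.markers, maf):
            m.maf = float(f)

    @property
    def n_lines(self) -> int:
        return len(self.lines)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def maf(self) -> np.ndarray:
        return np.array([m.maf for m in self.markers])

    def subset_markers(self, idx: np.ndarray) -> "GenotypePanel":
        idx = np.asarray(idx)
        markers = [self.markers[i] for i in idx]
        return GenotypePanel(self.lines, markers, self.calls[:, idx])

    def marker_ids(self) -> list[str]:
        return [m.id for m in self.markers]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypePanel):
            return NotImplemented
        if self.lines != other.lines:
            return False
        meta = [(m.id, m.chrom, m.pos, m.ref_allele, m.alt_allele) for m in self.markers]
        ometa = [(m.id, m.chrom, m.pos, m.ref_allele, m.alt_allele) for m in other.markers]
        if meta != ometa:
            return False
        return np.array_equal(self.calls, other.calls, equal_nan=True)


PHENOTYPE_COLUMNS = ["line", "diet", "trait", "replicate", "value"]


class PhenotypeTable:
    """Long-format replicate-level phenotype measurements.

    One row per (line, diet, trait, replicate); that key is unique and
    values are finite.  Backed by a pandas DataFrame (``.df``).
    """

    def __init__(self, df: pd.DataFrame):
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing columns: {missing}")
        df = df.copy()
        df["value"] = df["value"].astype(float)
        df["replicate"] = df["replicate"].astype(int)
        if not np.isfinite(df["value"]).all():
            raise ValueError("phenotype values must be finite")
        bad_diet = set(df["diet"]) - set(DIETS)
        if bad_diet:
            raise ValueError(f"unknown diet labels: {sorted(bad_diet)}")
        key = ["line", "diet", "trait", "replicate"]
        if df.duplicated(key).any():
            raise ValueError("(line, diet, trait, replicate) must be unique")
        self.df = df.reset_index(drop=True)

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.df["line"].unique())

    def __len__(self) -> int:
        return len(self.df)


class TraitMatrix:
    """Per-(line, diet, trait) replicate means.

    Backed by a long DataFrame with columns (line, diet, trait, value),
    one row per cell.  Scans consume aligned per-diet vectors via
    :meth:`pivot`.
    """

    def __init__(self, df: pd.DataFrame):
        for c in ("line", "diet", "trait", "value"):
            if c not in df.columns:
                raise ValueError(f"trait matrix missing column {c}")
        key = ["line", "diet", "trait"]
        if df.duplicated(key).any():
            raise ValueError("one cell per (line, diet, trait) required")
        self.df = df.reset_index(drop=True)[key + ["value"]]

    @property
    def traits(self) -> list[str]:
        return sorted(self.df["trait"].unique())

    @property
    def lines(self) -> list[str]:
        return sorted(self.df["line"].unique())

    def pivot(self, trait: str) -> pd.DataFrame:
        """Line x diet table of means for one trait (NaN where absent)."""
        sub = self.df[self.df["trait"] == trait]
        return sub.pivot(index="line", columns="diet", values="value")

    def trait_values(self, trait: str, diet: str, lines: list[str]) -> np.ndarray:
        """Values for one (trait, diet) aligned to ``lines`` (NaN if absent)."""
        sub = self.df[(self.df["trait"] == trait) & (self.df["diet"] == diet)]
        series = sub.set_index("line")["value"]
        return series.reindex(lines).to_numpy(dtype=float)

    def permute_lines(self, order: np.ndarray) -> "TraitMatrix":
        """Reassign each line's whole phenotype vector to another line.

        ``order`` is a permutation of ``range(n_lines)`` over the sorted
        line list: line i receives the phenotype vector of line order[i].
        All traits and both diets move together, so each diet's value
        multiset is preserved.
        """
        lines = self.lines
        mapping = {lines[int(src)]: lines[i] for i, src in enumerate(order)}
        df = self.df.copy()
        df["line"] = df["line"].map(mapping)
        return TraitMatrix(df)


@dataclass
class AssocResult:
    """Single-trait gene-by-diet fit at one marker.

    Model: y = b0 + b1*g + b2*d + b3*g*d with g the 0/1 homozygous
    genotype and d the 0/1 diet code (AL = 0, DR = 1).  ``p_genotype``
    and ``p_interaction`` are two-sided t-tests of b1 = 0 and b3 = 0 on
    n_used - 4 residual degrees of freedom.  ``r2_genotype_only`` is the
    R^2 of the genotype-only regression (variance explained, an upper
    bound via winner's-curse bias at selected loci).
    """

    marker_id: str
    intercept: float = float("nan")
    beta_genotype: float = float("nan")
    beta_diet: float = float("nan")
    beta_interaction: float = float("nan")
    se_intercept: float = float("nan")
    se_genotype: float = float("nan")
    se_diet: float = float("nan")
    se_interaction: float = float("nan")
    p_genotype: float = float("nan")
    p_interaction: float = float("nan")
    n_used: int = 0
    r2_genotype_only: float = float("nan")
    skip_reason: str | None = None
    saturated: bool = False


@dataclass
class CrossAssocResult:
    """Common-scaled-effect multi-trait test at one marker.

    ``statistic`` = estimate^2 / robust variance; ``p_joint`` from the
    1-df chi-square reference.
    """

    marker_id: str
    trait_pair: tuple[str, str]
    diet: str
    beta_common: float = float("nan")
    var_sandwich: float = float("nan")
    statistic: float = float("nan")
    p_joint: float = float("nan")
    max_r2: float = float("nan")
    n_used: int = 0
    skip_reason: str | None = None


@dataclass
class HeritabilityResult:
    """Broad-sense heritability H^2 = (s2_total - s2_intrastrain)/s2_total.

    Computed over lines with replicate measurements only; a negative
    estimate (intrastrain variance exceeding total) is reported as
    computed and flagged, never truncated.
    """

    trait: str
    diet: str | None
    sigma2_total: float
    sigma2_intrastrain: float
    h2: float
    n_lines: int
    flagged_negative: bool = field(init=False)

    def __post_init__(self) -> None:
        self.flagged_negative = self.h2 < 0


@dataclass
class EnrichmentResult:
    """Rank-based gene-set enrichment for one term.

    ``coefficient`` is the logistic coefficient on normalized gene rank;
    negative means members concentrate at the top (strong association).
    """

    term: str
    n_members_tested: int
    coefficient: float
    p: float
    q_bh: float = float("nan")
    fallback: bool = False


@dataclass
class FDRTable:
    """Permutation-estimated FDR over a grid of p-value thresholds.

    fdr_raw(t) = mean over permutations of the number of markers called
    at t, divided by the number called on the real data; NaN where no
    real calls exist.  ``fdr`` caps the ratio at 1 for reporting.
    """

    thresholds: np.ndarray
    n_real: np.ndarray
    mean_n_perm: np.ndarray
    fdr_raw: np.ndarray
    n_permutations: int
    seed: int

    @property
    def fdr(self) -> np.ndarray:
        return np.minimum(self.fdr_raw, 1.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.thresholds,
                "n_real": self.n_real,
                "mean_n_perm": self.mean_n_perm,
                "fdr": self.fdr,
                "fdr_raw": self.fdr_raw,
            }
        )
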