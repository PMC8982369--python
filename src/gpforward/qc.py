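"""Genotype panel container, marker/animal quality control, and pairwise LD.

The panel is an animals x SNPs dosage matrix (0/1/2, ``NaN`` for missing)
with an ordered SNP map. QC applies, in a fixed order: animal call-rate
removal, per-SNP MAF and call-rate filters, then a single forward scan per
chromosome that prunes one member (seeded choice) of every adjacent pair of
retained SNPs whose dosage correlation exceeds the threshold.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, QcError

__all__ = ["GenotypePanel", "QcReport", "qc_filter", "ld_r2", "impute_mean"]


@dataclass
class GenotypePanel:
    """Dosage matrix with row (animal) and column (SNP) identity and a SNP map.

    Parameters
    ----------
    animal_ids : sequence of str
        Row labels, one per animal.
    snp_ids : sequence of str
        Column labels, one per SNP, in map order.
    dosages : ndarray of shape (n_animals, n_snps)
        Allele dosages in ``{0, 1, 2}``; ``NaN`` encodes a missing call.
        Fractional values are permitted after mean imputation.
    snp_map : pandas.DataFrame
        Columns ``snp_id``, ``chrom``, ``cm``; positions strictly
        increasing within each chromosome, rows aligned with ``snp_ids``.
    """

    animal_ids: np.ndarray
    snp_ids: np.ndarray
    dosages: np.ndarray
    snp_map: pd.DataFrame

    def __post_init__(self):
        self.animal_ids = np.asarray(self.animal_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ParameterError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.animal_ids)} animals x {len(self.snp_ids)} SNPs"
            )
        if not np.array_equal(
            np.asarray(self.snp_map["snp_id"], dtype=object), self.snp_ids
        ):
            raise ParameterError("snp_map rows are not aligned with snp_ids")
        with np.errstate(invalid="ignore"):
            bad = (self.dosages < 0) | (self.dosages > 2)
        if bad.any():
            raise ParameterError("dosages must lie in [0, 2] or be NaN")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            pos = np.asarray(grp["cm"], dtype=float)
            if not np.all(np.diff(pos) > 0):
                raise ParameterError(
                    "genetic positions must be strictly increasing per chromosome"
                )

    # -- basic accessors -------------------------------------------------
    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def allele_freq(self) -> np.ndarray:
        """Per-SNP allele frequency of the counted allele (mean dosage / 2)."""
        return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=0)

    def animal_call_rate(self) -> np.ndarray:
        return 1.0 - np.mean(np.isnan(self.dosages), axis=1)

    def subset(self, animal_idx=None, snp_idx=None) -> "GenotypePanel":
        """Return a new panel restricted to the given row/column indices."""
        a = np.arange(self.n_animals) if animal_idx is None else np.asarray(animal_idx)
        s = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypePanel(
            animal_ids=self.animal_ids[a],
            snp_ids=self.snp_ids[s],
            dosages=self.dosages[np.ix_(a, s)],
            snp_map=self.snp_map.iloc[s].reset_index(drop=True),
        )

    def subset_ids(self, animal_ids=None, snp_ids=None) -> "GenotypePanel":
        a_idx = None
        s_idx = None
        if animal_ids is not None:
            lookup = {a: i for i, a in enumerate(self.animal_ids)}
            a_idx = np.array([lookup[a] for a in animal_ids])
        if snp_ids is not None:
            lookup = {s: i for i, s in enumerate(self.snp_ids)}
            s_idx = np.array([lookup[s] for s in snp_ids])
        return self.subset(a_idx, s_idx)


@dataclass
class QcReport:
    """Tally of removals per QC rule plus the surviving identifiers."""

    n_removed_animals: int = 0
    n_removed_maf: int = 0
    n_removed_callrate_snp: int = 0
    n_removed_ld: int = 0
    surviving_animals: list = field(default_factory=list)
    surviving_snps: list = field(default_factory=list)
    removed_animals: list = field(default_factory=list)
    removed_snps_maf: list = field(default_factory=list)
    removed_snps_callrate: list = field(default_factory=list)
    removed_snps_ld: list = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, default=str)


def _pairwise_complete_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r over entries observed in both vectors; NaN if undefined."""
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 2:
        return np.nan
    xs, ys = x[ok], y[ok]
    sx, sy = xs.std(), ys.std()
    if sx == 0 or sy == 0:
        return np.nan
    return float(np.mean((xs - xs.mean()) * (ys - ys.mean())) / (sx * sy))


def qc_filter(
    panel: GenotypePanel,
    maf_min: float = 0.05,
    snp_callrate_min: float = 0.90,
    adjacent_r_max: float = 0.80,
    animal_callrate_min: float = 0.90,
    seed: int = 0,
) -> tuple[GenotypePanel, QcReport]:
    """Apply marker and animal QC filters in a fixed, documented order.

    Order: (1) animals with call rate below ``animal_callrate_min`` are
    removed; (2) SNPs failing the MAF or SNP call-rate threshold are
    removed (MAF computed after animal removal); (3) within each
    chromosome a single forward scan compares each retained SNP with the
    next retained SNP and, when ``|r|`` exceeds ``adjacent_r_max``, removes
    one of the pair uniformly at random (seeded).

    Returns the filtered panel and a :class:`QcReport`. Raises
    :class:`~gpforward.exceptions.QcError` if nothing survives.
    """
    for name, v in {
        "maf_min": maf_min,
        "snp_callrate_min": snp_callrate_min,
        "adjacent_r_max": adjacent_r_max,
        "animal_callrate_min": animal_callrate_min,
    }.items():
        if not 0.0 <= v <= 1.0:
            raise ParameterError(f"{name}={v} outside [0, 1]")

    rng = np.random.default_rng(seed)
    report = QcReport(
        thresholds={
            "maf_min": maf_min,
            "snp_callrate_min": snp_callrate_min,
            "adjacent_r_max": adjacent_r_max,
            "animal_callrate_min": animal_callrate_min,
            "seed": seed,
        }
    )

    # 1. animal call rate
    keep_a = panel.animal_call_rate() >= animal_callrate_min
    report.removed_animals = list(panel.animal_ids[~keep_a])
    report.n_removed_animals = int((~keep_a).sum())
    if not keep_a.any():
        raise QcError("no animals survive the call-rate filter", report)
    panel = panel.subset(animal_idx=np.flatnonzero(keep_a))

    # 2. SNP call rate and MAF (on the surviving animals)
    cr = panel.snp_call_rate()
    maf = panel.maf()
    fail_cr = cr < snp_callrate_min
    # no observed call at all -> undefined MAF, counted under call rate
    fail_maf = ~fail_cr & (np.isnan(maf) | (maf < maf_min))
    report.removed_snps_callrate = list(panel.snp_ids[fail_cr])
    report.removed_snps_maf = list(panel.snp_ids[fail_maf])
    report.n_removed_callrate_snp = int(fail_cr.sum())
    report.n_removed_maf = int(fail_maf.sum())
    keep_s = ~(fail_cr | fail_maf)
    if not keep_s.any():
        raise QcError("no SNPs survive MAF/call-rate filters", report)
    panel = panel.subset(snp_idx=np.flatnonzero(keep_s))

    # 3. adjacent-LD prune, forward scan per chromosome on |r|
    removed_ld: list[int] = []
    chroms = np.asarray(panel.snp_map["chrom"])
    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        anchor = idx[0]
        for j in idx[1:]:
            r = _pairwise_complete_corr(panel.dosages[:, anchor], panel.dosages[:, j])
            if np.isfinite(r) and abs(r) > adjacent_r_max:
                victim = anchor if rng.random() < 0.5 else j
                removed_ld.append(victim)
                anchor = j if victim == anchor else anchor
            else:
                anchor = j
    removed_ld = sorted(removed_ld)
    report.removed_snps_ld = list(panel.snp_ids[removed_ld])
    report.n_removed_ld = len(removed_ld)
    keep = np.setdiff1d(np.arange(panel.n_snps), removed_ld)
    if keep.size == 0:
        raise QcError("no SNPs survive adjacent-LD pruning", report)
    panel = panel.subset(snp_idx=keep)

    report.surviving_animals = list(panel.animal_ids)
    report.surviving_snps = list(panel.snp_ids)
    return panel, report


def ld_r2(panel: GenotypePanel, pairs) -> np.ndarray:
    """Squared Pearson correlation of dosages for each (i, j) SNP index pair.

    Computed over animals with observed calls at both SNPs. Raises
    :class:`~gpforward.exceptions.ParameterError` when either SNP has zero
    variance on the pairwise-complete subset (LD undefined).
    """
    out = np.empty(len(pairs))
    for k, (i, j) in enumerate(pairs):
        r = _pairwise_complete_corr(panel.dosages[:, i], panel.dosages[:, j])
        if not np.isfinite(r):
            raise ParameterError(
                f"LD undefined for SNP pair ({panel.snp_ids[i]}, {panel.snp_ids[j]}): "
                "zero variance or no shared calls"
            )
        out[k] = r * r
    return out


def impute_mean(panel: GenotypePanel) -> GenotypePanel:
    """Replace missing dosages by the per-SNP observed mean (fractional).

    A SNP with no observed call at all cannot be imputed and raises; such
    a column should have been removed by the call-rate filter.
    """
    d = panel.dosages.copy()
    n_obs = (~np.isnan(d)).sum(axis=0)
    if (n_obs == 0).any():
        bad = panel.snp_ids[n_obs == 0]
        raise ParameterError(f"SNPs with no observed calls cannot be imputed: {list(bad)}")
    col_mean = np.nanmean(d, axis=0)
    miss = np.isnan(d)
    d[miss] = np.broadcast_to(col_mean, d.shape)[miss]
    return GenotypePanel(
        animal_ids=panel.animal_ids.copy(),
        snp_ids=panel.snp_ids.copy(),
        dosages=d,
        snp_map=panel.snp_map.copy(),
    )
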