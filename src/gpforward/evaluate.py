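"""Evaluation designs: forward validation, generation-gap scenarios,
importance-based marker preselection, and model-similarity analyses.

The central design is forward prediction: older generations form the
reference set, the youngest generation the validation set. Accuracy is
the Pearson correlation between predictions and precorrected phenotypes;
RRMSE is the root mean squared error divided by the phenotypic SD. Gap
scenarios resample a fixed-size reference (N=300 by default) with
per-generation quotas proportional to the NoGAP representation, dropping
the generations closest to validation. All models in a replicate see the
same sampled reference.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DesignError, ParameterError
from .gbm import GbmConfig, feature_importance, fit_gbm, predict_gbm, tune_gbm
from .linear import (
    BayesBConfig,
    EnetConfig,
    GblupConfig,
    LinearFit,
    backsolve_snp_effects,
    fit_bayesb,
    fit_enet,
    fit_gblup,
    tune_enet,
)
from .pheno import TraitTable, build_g_additive, standardize_genotypes
from .qc import GenotypePanel

__all__ = [
    "ScenarioSpec",
    "OverlapResult",
    "forward_split",
    "accuracy",
    "bootstrap_ci",
    "rrmse",
    "default_configs",
    "fit_and_predict",
    "run_forward_evaluation",
    "run_gap_scenarios",
    "preselect_and_refit",
    "top_animal_overlap",
    "snp_rank_overlap",
    "report",
    "scenario_quotas",
]

log = logging.getLogger(__name__)

MODELS = ("gblup", "bayesb", "enet", "gbm")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def accuracy(ystar, yhat) -> float:
    """Pearson correlation between precorrected phenotypes and predictions."""
    y = np.asarray(ystar, dtype=float)
    p = np.asarray(yhat, dtype=float)
    if y.size != p.size or y.size < 3:
        raise ParameterError("accuracy needs >= 3 paired values")
    if y.std() == 0 or p.std() == 0:
        raise ParameterError("correlation undefined for a constant vector")
    return float(np.corrcoef(y, p)[0, 1])


def bootstrap_ci(ystar, yhat, n_boot: int = 1000, seed: int = 0) -> dict:
    """Bootstrap (resampling animal pairs) SD and percentile interval for accuracy."""
    y = np.asarray(ystar, dtype=float)
    p = np.asarray(yhat, dtype=float)
    rng = np.random.default_rng(seed)
    n = y.size
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        ys, ps = y[idx], p[idx]
        if ys.std() == 0 or ps.std() == 0:
            continue
        stats.append(np.corrcoef(ys, ps)[0, 1])
    stats = np.asarray(stats)
    return {
        "sd": float(stats.std()),
        "low": float(np.percentile(stats, 2.5)),
        "high": float(np.percentile(stats, 97.5)),
        "n_boot": int(stats.size),
    }


def rrmse(ystar, yhat, sigma_p: float) -> float:
    """Root mean squared prediction error relative to the phenotypic SD."""
    if sigma_p <= 0:
        raise ParameterError("sigma_p must be positive")
    y = np.asarray(ystar, dtype=float)
    p = np.asarray(yhat, dtype=float)
    return float(np.sqrt(np.mean((y - p) ** 2)) / sigma_p)


# ---------------------------------------------------------------------------
# splits and scenarios
# ---------------------------------------------------------------------------

def forward_split(traits: TraitTable, validation_generation=11, trait: str | None = None):
    """Partition animals by generation into (reference_ids, validation_ids).

    Animals missing the given trait (raw value) are dropped from the
    relevant side. Validation is the single ``validation_generation``;
    everything older is reference.
    """
    df = traits.data
    gens = df["generation"]
    if validation_generation not in set(gens):
        raise DesignError(f"generation {validation_generation} absent from data")
    observed = (
        pd.to_numeric(df[trait], errors="coerce").notna()
        if trait is not None
        else pd.Series(True, index=df.index)
    )
    val = df.loc[(gens == validation_generation) & observed, "animal_id"]
    ref = df.loc[(gens != validation_generation) & observed, "animal_id"]
    if len(val) == 0:
        raise DesignError("validation set is empty")
    return list(ref), list(val)


@dataclass
class ScenarioSpec:
    """One generation-gap scenario with a quota-constrained reference sample."""

    name: str
    reference_generations: tuple
    validation_generation: int = 11
    sample_size: int = 300
    n_replicates: int = 20

    @staticmethod
    def default_scenarios(sample_size: int = 300, n_replicates: int = 20):
        return [
            ScenarioSpec("NoGAP", (4, 5, 7, 8, 9), 11, sample_size, n_replicates),
            ScenarioSpec("GAP9", (4, 5, 7, 8), 11, sample_size, n_replicates),
            ScenarioSpec("GAP89", (4, 5, 7), 11, sample_size, n_replicates),
        ]


def scenario_quotas(spec: ScenarioSpec, nogap_counts: dict) -> dict:
    """Per-generation quotas by largest-remainder rounding.

    Weights are each included generation's animal count in the NoGAP
    reference pool, so the sampled reference keeps the NoGAP
    representativeness (renormalized over the scenario's generations).
    """
    gens = [g for g in spec.reference_generations if g in nogap_counts]
    if not gens:
        raise DesignError("no reference generations available for quotas")
    w = np.array([nogap_counts[g] for g in gens], dtype=float)
    raw = spec.sample_size * w / w.sum()
    quotas = np.floor(raw).astype(int)
    remainder = spec.sample_size - quotas.sum()
    order = np.lexsort((np.arange(len(gens)), -(raw - np.floor(raw))))
    for i in order[:remainder]:
        quotas[i] += 1
    out = dict(zip(gens, quotas.tolist()))
    for g, q in out.items():
        if q > nogap_counts[g]:
            raise DesignError(
                f"quota {q} exceeds available animals ({nogap_counts[g]}) in generation {g}"
            )
    return out


# ---------------------------------------------------------------------------
# model dispatch
# ---------------------------------------------------------------------------

def default_configs() -> dict:
    """Desk-scale model configurations (paper-fidelity chains via the
    dataclasses' own defaults)."""
    return {
        "gblup": GblupConfig.desk(),
        "bayesb": BayesBConfig.desk(),
        "enet": EnetConfig(alpha=0.5, lambda_total=0.05),
        "gbm": GbmConfig(ntree=200, learning_rate=0.1, max_depth=3),
    }


@dataclass
class _Workspace:
    """Precomputed shared matrices for one panel + animal ordering."""

    panel: GenotypePanel
    Z: np.ndarray
    G: object
    row_of: dict

    @classmethod
    def build(cls, panel: GenotypePanel):
        z, _ = standardize_genotypes(panel.dosages)
        g = build_g_additive(panel)
        return cls(panel=panel, Z=z, G=g, row_of={a: i for i, a in enumerate(panel.animal_ids)})

    def rows(self, ids):
        return np.array([self.row_of[a] for a in ids])


def fit_and_predict(
    model: str,
    ystar: pd.Series,
    ref_ids,
    val_ids,
    ws: _Workspace,
    config=None,
    seed: int = 0,
):
    """Fit one model on the reference animals and predict the validation set.

    Returns ``(predictions over val_ids, fit object)``. GBLUP uses the
    relationship matrix; BayesB and the elastic net use standardized
    genotypes; GBM uses raw dosages.
    """
    y_ref = ystar.loc[list(ref_ids)].to_numpy(float)
    r_rows, v_rows = ws.rows(ref_ids), ws.rows(val_ids)
    if model == "gblup":
        fit = fit_gblup(y_ref, ws.G, ref_ids, cfg=config, seed=seed)
        pred = fit.predict(ids=val_ids)
    elif model == "bayesb":
        fit = fit_bayesb(y_ref, ws.Z[r_rows], cfg=config, seed=seed)
        pred = fit.predict(Z=ws.Z[v_rows])
    elif model == "enet":
        fit = fit_enet(y_ref, ws.Z[r_rows], cfg=config)
        pred = fit.predict(Z=ws.Z[v_rows])
    elif model == "gbm":
        fit = fit_gbm(y_ref, ws.panel.dosages[r_rows], cfg=config, seed=seed)
        pred = predict_gbm(fit, ws.panel.dosages[v_rows])
    else:
        raise ParameterError(f"unknown model {model!r}")
    return pd.Series(pred, index=pd.Index(list(val_ids))), fit


# ---------------------------------------------------------------------------
# headline forward evaluation
# ---------------------------------------------------------------------------

def run_forward_evaluation(
    panel: GenotypePanel,
    traits: TraitTable,
    trait_names=None,
    models=MODELS,
    validation_generation=11,
    configs: dict | None = None,
    seed: int = 0,
    n_boot: int = 1000,
    sigma_p_scope: str = "full",
):
    """Forward-validation accuracy and RRMSE per trait x model.

    Returns ``(results DataFrame, predictions, fits)`` where predictions
    and fits are nested dicts keyed by trait then model (fits are needed
    for the downstream overlap analyses).
    """
    configs = configs or default_configs()
    trait_names = list(trait_names or traits.trait_names)
    ws = _Workspace.build(panel)
    rows, predictions, fits = [], {}, {}
    for t_i, trait in enumerate(trait_names):
        ref_ids, val_ids = forward_split(traits, validation_generation, trait)
        ystar = traits.ystar_vector(trait)
        scope_ids = ref_ids + val_ids if sigma_p_scope == "full" else val_ids
        sigma_p = float(ystar.loc[scope_ids].std())
        y_val = ystar.loc[val_ids].to_numpy(float)
        predictions[trait], fits[trait] = {}, {}
        for m_i, model in enumerate(models):
            pred, fit = fit_and_predict(
                model, ystar, ref_ids, val_ids, ws,
                config=configs.get(model), seed=seed + 1000 * t_i + m_i,
            )
            acc = accuracy(y_val, pred.to_numpy())
            boot = bootstrap_ci(y_val, pred.to_numpy(), n_boot=n_boot, seed=seed + 77)
            rows.append(
                {
                    "trait": trait, "model": model, "scenario": "full",
                    "n_reference": len(ref_ids), "n_validation": len(val_ids),
                    "accuracy": acc, "accuracy_boot_sd": boot["sd"],
                    "accuracy_ci_low": boot["low"], "accuracy_ci_high": boot["high"],
                    "rrmse": rrmse(y_val, pred.to_numpy(), sigma_p),
                }
            )
            predictions[trait][model] = pred
            fits[trait][model] = fit
    return pd.DataFrame(rows), predictions, fits


def run_gap_scenarios(
    panel: GenotypePanel,
    traits: TraitTable,
    trait: str,
    models=MODELS,
    scenarios=None,
    configs: dict | None = None,
    seed: int = 0,
    sigma_p_scope: str = "full",
):
    """Replicated quota-constrained reference sampling per gap scenario.

    Each replicate draws one reference sample per scenario (seeded) and
    fits every requested model on that same sample, predicting the fixed
    validation generation. Returns ``(replicates DataFrame, summary
    DataFrame)`` with replicate-level and mean/SD accuracy and RRMSE.
    """
    configs = configs or default_configs()
    scenarios = scenarios or ScenarioSpec.default_scenarios()
    ws = _Workspace.build(panel)
    ystar = traits.ystar_vector(trait)

    nogap_gens = scenarios[0].reference_generations
    ref_all, val_ids = forward_split(traits, scenarios[0].validation_generation, trait)
    gen_of = dict(zip(traits.data["animal_id"], traits.data["generation"]))
    pool = {g: [a for a in ref_all if gen_of[a] == g] for g in nogap_gens}
    nogap_counts = {g: len(v) for g, v in pool.items() if len(v) > 0}
    sigma_p = float(
        ystar.loc[ref_all + val_ids].std() if sigma_p_scope == "full"
        else ystar.loc[val_ids].std()
    )
    y_val = ystar.loc[val_ids].to_numpy(float)

    rows = []
    for spec in scenarios:
        quotas = scenario_quotas(spec, nogap_counts)
        for rep in range(spec.n_replicates):
            name_tag = zlib.crc32(spec.name.encode())  # stable across runs
            rng = np.random.default_rng([seed, name_tag, rep])
            sample = []
            for g in sorted(quotas):
                sample.extend(sorted(rng.choice(pool[g], size=quotas[g], replace=False)))
            for m_i, model in enumerate(models):
                pred, _ = fit_and_predict(
                    model, ystar, sample, val_ids, ws,
                    config=configs.get(model), seed=seed + 13 * rep + m_i,
                )
                rows.append(
                    {
                        "scenario": spec.name, "trait": trait, "model": model,
                        "replicate": rep,
                        "accuracy": accuracy(y_val, pred.to_numpy()),
                        "rrmse": rrmse(y_val, pred.to_numpy(), sigma_p),
                    }
                )
    reps = pd.DataFrame(rows)
    summary = (
        reps.groupby(["scenario", "trait", "model"], sort=False)
        .agg(
            accuracy_mean=("accuracy", "mean"), accuracy_sd=("accuracy", "std"),
            rrmse_mean=("rrmse", "mean"), rrmse_sd=("rrmse", "std"),
            n_replicates=("replicate", "count"),
        )
        .reset_index()
    )
    return reps, summary


# ---------------------------------------------------------------------------
# importance-based preselection
# ---------------------------------------------------------------------------

def preselect_and_refit(
    panel: GenotypePanel,
    traits: TraitTable,
    trait: str,
    subset_sizes=(100, 250, 500, 1000),
    models=("gblup", "enet", "gbm"),
    configs: dict | None = None,
    seed: int = 0,
    validation_generation=11,
    importance_config: GbmConfig | None = None,
    gbm_grids: dict | None = None,
    sigma_p_scope: str = "full",
):
    """Refit models on the top-k SNPs ranked by GBM importance.

    The importance source is a GBM fit on reference data only (tuned on
    the internal 80-20 split unless ``importance_config`` pins a
    configuration). Requested subset sizes larger than the number of SNPs
    with nonzero importance resolve to that number, labeled in the
    output. Returns a results DataFrame.
    """
    if min(subset_sizes) < 2:
        raise ParameterError("subset sizes must be >= 2")
    configs = configs or default_configs()
    ref_ids, val_ids = forward_split(traits, validation_generation, trait)
    ystar = traits.ystar_vector(trait)
    y_ref = ystar.loc[ref_ids].to_numpy(float)
    y_val = ystar.loc[val_ids].to_numpy(float)
    scope_ids = ref_ids + val_ids if sigma_p_scope == "full" else val_ids
    sigma_p = float(ystar.loc[scope_ids].std())

    full_rows = {a: i for i, a in enumerate(panel.animal_ids)}
    r_rows = np.array([full_rows[a] for a in ref_ids])
    x_ref = panel.dosages[r_rows]

    if importance_config is not None:
        source = fit_gbm(y_ref, x_ref, importance_config, seed=seed)
    else:
        grids = gbm_grids or {}
        source = tune_gbm(y_ref, x_ref, seed=seed, **grids).fit
    ranking = feature_importance(source)

    rows = []
    for size in sorted(set(int(s) for s in subset_sizes)):
        actual = min(size, max(ranking.n_nonzero, 2), panel.n_snps)
        top_idx = np.sort(ranking.order[:actual])
        sub = panel.subset(snp_idx=top_idx)
        ws = _Workspace.build(sub)
        for m_i, model in enumerate(models):
            pred, _ = fit_and_predict(
                model, ystar, ref_ids, val_ids, ws,
                config=configs.get(model), seed=seed + 31 * size + m_i,
            )
            rows.append(
                {
                    "trait": trait, "model": model,
                    "subset_label": f"SNP{size}", "requested_size": size,
                    "actual_size": int(actual),
                    "accuracy": accuracy(y_val, pred.to_numpy()),
                    "rrmse": rrmse(y_val, pred.to_numpy(), sigma_p),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# overlap analyses
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    """Directional top-K SNP overlap between an ordered model pair."""

    model_a: str
    model_b: str
    top_k: int
    k_used_a: int
    k_used_b: int
    overlap: int
    r2_threshold: float


def _top_ids(pred: pd.Series, k: int):
    order = sorted(pred.index, key=lambda a: (-pred.loc[a], str(a)))
    return order[:k]


def top_animal_overlap(predictions: dict, k: int = 20) -> dict:
    """Venn-style intersection counts of the top-k predicted animals per model.

    Returns ``top_sets`` (per model), exclusive ``region_counts`` keyed by
    the sorted tuple of models sharing those animals, and ``pair_counts``
    with plain pairwise intersections.
    """
    models = list(predictions)
    n_val = {m: len(p) for m, p in predictions.items()}
    if len(set(map(tuple, (sorted(p.index) for p in predictions.values())))) != 1:
        raise ParameterError("all models must predict the same validation set")
    if k > min(n_val.values()):
        raise ParameterError(f"k={k} exceeds validation size {min(n_val.values())}")
    tops = {m: set(_top_ids(predictions[m], k)) for m in models}
    region_counts: dict = {}
    universe = set().union(*tops.values())
    for animal in universe:
        members = tuple(sorted(m for m in models if animal in tops[m]))
        region_counts[members] = region_counts.get(members, 0) + 1
    pair_counts = {
        (a, b): len(tops[a] & tops[b]) for a in models for b in models
    }
    return {
        "top_sets": {m: sorted(tops[m], key=str) for m in models},
        "region_counts": region_counts,
        "pair_counts": pair_counts,
        "k": k,
    }


def snp_rank_overlap(
    scores: dict,
    panel: GenotypePanel,
    k: int = 1000,
    r2_threshold: float = 0.90,
) -> list:
    """Directional top-K SNP overlap with an LD equivalence.

    ``scores`` maps model name to a per-SNP score vector aligned with
    ``panel.snp_ids`` (squared effects for linear models, importance for
    GBM). For each ordered pair (A, B), a top-K SNP of A counts as
    overlapping when it is in B's top-K or has ``r^2`` above the threshold
    with at least one of B's top-K SNPs, computed on this panel. Models
    with fewer than K scored (nonzero) SNPs contribute all their scored
    SNPs, reflected in ``k_used``.
    """
    models = list(scores)
    tops = {}
    for m in models:
        s = np.asarray(scores[m], dtype=float)
        if s.size != panel.n_snps:
            raise ParameterError(f"score vector for {m!r} does not match panel")
        order = np.lexsort((np.arange(s.size), -s))
        nonzero = int((s > 0).sum())
        k_used = min(k, nonzero) if nonzero else min(k, s.size)
        tops[m] = order[:k_used]

    x = panel.dosages
    xc = x - np.nanmean(x, axis=0)
    norms = np.sqrt(np.nansum(xc**2, axis=0))

    results = []
    for a in models:
        for b in models:
            ta, tb = tops[a], tops[b]
            set_b = set(tb.tolist())
            shared = np.array([i in set_b for i in ta])
            count = int(shared.sum())
            rest = ta[~shared]
            if rest.size and len(tb):
                va = np.where(norms[rest] > 0, norms[rest], np.inf)
                vb = np.where(norms[tb] > 0, norms[tb], np.inf)
                corr = (xc[:, rest].T @ xc[:, tb]) / np.outer(va, vb)
                count += int(((corr**2) > r2_threshold).any(axis=1).sum())
            results.append(
                OverlapResult(
                    model_a=a, model_b=b, top_k=k,
                    k_used_a=len(ta), k_used_b=len(tb),
                    overlap=count, r2_threshold=r2_threshold,
                )
            )
    return results


def model_snp_scores(fit, ws: _Workspace) -> np.ndarray:
    """Per-SNP ranking score for any fitted model.

    GBLUP effects are back-solved from the genetic values first; GBM uses
    its importance scores; BayesB and the elastic net use their estimated
    effects. Scores are squared effects for linear models.
    """
    if isinstance(fit, LinearFit):
        if fit.model == "gblup" and fit.beta is None:
            backsolve_snp_effects(fit, ws.Z, ws.G)
        return fit.snp_scores()
    return feature_importance(fit).scores


# ---------------------------------------------------------------------------
# report emission
# ---------------------------------------------------------------------------

def report(slices: dict, out_dir, manifest: dict | None = None) -> dict:
    """Write evaluation slices as CSV tables plus a JSON bundle.

    ``slices`` maps section name to a DataFrame (written as
    ``<name>.csv``) or a JSON-serializable object (collected into
    ``results.json``). Empty/None sections are omitted. Returns the paths
    written. Output is deterministic for identical inputs.
    """
    import pathlib

    if not slices:
        raise ParameterError("nothing to report")
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    json_bundle = {}
    for name, obj in sorted(slices.items()):
        if obj is None:
            continue
        if isinstance(obj, pd.DataFrame):
            if obj.empty:
                continue
            path = out / f"{name}.csv"
            obj.to_csv(path, index=False, float_format="%.10g")
            written[name] = str(path)
        else:
            json_bundle[name] = obj
    if json_bundle or manifest:
        path = out / "results.json"
        with open(path, "w") as fh:
            json.dump(json_bundle, fh, indent=2, sort_keys=True, default=str)
        written["results"] = str(path)
    if manifest is not None:
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        written["manifest"] = str(path)
    return written
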