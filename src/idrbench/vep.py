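"""Region-stratified evaluation of variant effect predictors (VEPs).

Given a set of region-assigned variants (pathogenic from clinical
annotation, putatively benign from population data) and per-VEP score maps,
this module measures how well each VEP separates the two classes globally
and within disordered / intermediate / ordered regions:

* coverage filtering (a VEP must score at least 75% of variants by default),
  then intersection to the variants scored by *every* retained VEP, so that
  all predictors are compared on the same set;
* AUROC (rank / Mann-Whitney formulation, ties counted one half);
* Youden-J-optimal decision thresholds, global and per region, with the
  resulting sensitivity and specificity;
* Cohen's kappa agreement between every VEP pair, summarised within and
  between VEP groups (clinical-trained / population-tuned / population-free).

Conventions used consistently throughout: after orientation, higher score
means more pathogenic; the call rule is pathogenic iff score >= threshold;
candidate thresholds are the observed score values plus +inf; Youden ties
prefer higher sensitivity, then the lower threshold.

The user-facing entry point is the model/results pair
:class:`VepBenchmark` / :class:`VepBenchmarkResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from itertools import combinations

import numpy as np
import pandas as pd
import yaml

from .structure import REGION_LABELS

logger = logging.getLogger(__name__)

VEP_GROUPS = ("clinical_trained", "population_tuned", "population_free")
SCOPES = ("global",) + REGION_LABELS

VariantKey = tuple[str, int, str, str]  # (protein_id, position, ref_aa, alt_aa)


@dataclass
class VepScoreSet:
    """One predictor's scores over variants, with orientation metadata."""

    name: str
    group: str
    higher_is_pathogenic: bool
    scores: dict[VariantKey, float]

    def __post_init__(self) -> None:
        if self.group not in VEP_GROUPS:
            raise ValueError(
                f"{self.name}: unknown group {self.group!r}; allowed: {', '.join(VEP_GROUPS)}"
            )
        for key, value in self.scores.items():
            if not math.isfinite(value):
                raise ValueError(f"{self.name}: non-finite score for {key}")


@dataclass(frozen=True)
class EvaluationDataset:
    """Complete score matrix over retained VEPs x retained variants.

    ``variants`` carries one row per retained variant with a binary
    ``outcome`` (1 = pathogenic, 0 = putatively benign) and its ``region``;
    ``scores`` has the same row order, one oriented column per VEP.
    """

    variants: pd.DataFrame
    scores: pd.DataFrame
    groups: dict[str, str]

    @property
    def vep_names(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def outcomes(self) -> np.ndarray:
        return self.variants["outcome"].to_numpy(dtype=int)

    def region_mask(self, scope: str) -> np.ndarray:
        if scope == "global":
            return np.ones(len(self.variants), dtype=bool)
        return (self.variants["region"] == scope).to_numpy()


@dataclass(frozen=True)
class ThresholdResult:
    vep: str
    scope: str
    threshold: float
    J: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class KappaResult:
    scope: str
    group_pair: tuple[str, str]
    mean_kappa: float
    sem: float | None
    n_pairs: int


# ---------------------------------------------------------------------------
# score-table input
# ---------------------------------------------------------------------------

def load_vep_metadata(path) -> dict[str, dict]:
    """YAML mapping of VEP name -> {group, higher_is_pathogenic}."""
    with open(path) as fh:
        meta = yaml.safe_load(fh)
    if not isinstance(meta, dict) or not meta:
        raise ValueError(f"{path}: expected a non-empty mapping of VEP metadata")
    for name, entry in meta.items():
        if "group" not in entry or "higher_is_pathogenic" not in entry:
            raise ValueError(f"{path}: VEP {name!r} needs group and higher_is_pathogenic")
    return meta


def load_scores_long(path, metadata: dict[str, dict]) -> list[VepScoreSet]:
    """Long-form score TSV: vep, protein_id, position, ref_aa, alt_aa, score."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"vep", "protein_id", "position", "ref_aa", "alt_aa", "score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    scoresets = []
    for name, sub in df.groupby("vep", sort=True):
        if name not in metadata:
            raise ValueError(f"{path}: no metadata for VEP {name!r}")
        scores = {
            (r.protein_id, int(r.position), r.ref_aa, r.alt_aa): float(r.score)
            for r in sub.itertuples(index=False)
        }
        scoresets.append(
            VepScoreSet(
                name=str(name),
                group=metadata[name]["group"],
                higher_is_pathogenic=bool(metadata[name]["higher_is_pathogenic"]),
                scores=scores,
            )
        )
    return scoresets


def load_scores_wide(path, metadata: dict[str, dict]) -> list[VepScoreSet]:
    """Wide-form score TSV: one column per VEP, empty cell = missing score."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    key_cols = ["protein_id", "position", "ref_aa", "alt_aa"]
    missing = set(key_cols) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing key columns {sorted(missing)}")
    vep_cols = [c for c in df.columns if c not in key_cols]
    scoresets = []
    for name in vep_cols:
        if name not in metadata:
            raise ValueError(f"{path}: no metadata for VEP {name!r}")
        sub = df.loc[df[name].notna()]
        scores = {
            (r.protein_id, int(r.position), r.ref_aa, r.alt_aa): float(getattr(r, name))
            for r in sub.itertuples(index=False)
        }
        scoresets.append(
            VepScoreSet(
                name=name,
                group=metadata[name]["group"],
                higher_is_pathogenic=bool(metadata[name]["higher_is_pathogenic"]),
                scores=scores,
            )
        )
    return scoresets


# ---------------------------------------------------------------------------
# filtering (order is normative: VEP coverage first, then variant intersection)
# ---------------------------------------------------------------------------

def variant_keys(variants: pd.DataFrame) -> list[VariantKey]:
    return [
        (r.protein_id, int(r.position), r.ref_aa, r.alt_aa)
        for r in variants.itertuples(index=False)
    ]


def filter_by_coverage(
    scoresets: list[VepScoreSet], variants: pd.DataFrame, min_frac: float = 0.75
) -> tuple[list[VepScoreSet], dict[str, float]]:
    """Retain VEPs scoring at least ``min_frac`` (inclusive) of the variants."""
    keys = variant_keys(variants)
    if not keys:
        raise ValueError("no variants to compute coverage against")
    coverage = {
        s.name: sum(1 for k in keys if k in s.scores) / len(keys) for s in scoresets
    }
    retained = [s for s in scoresets if coverage[s.name] >= min_frac]
    for s in scoresets:
        logger.info(
            "VEP %s coverage %.3f -> %s", s.name, coverage[s.name],
            "retained" if coverage[s.name] >= min_frac else "dropped",
        )
    if not retained:
        raise ValueError(
            f"no VEP reaches the {min_frac:.0%} coverage requirement "
            f"(best: {max(coverage.values()):.3f})"
        )
    return retained, coverage


def intersect_complete(
    variants: pd.DataFrame, scoresets: list[VepScoreSet]
) -> EvaluationDataset:
    """Keep exactly the variants scored by every retained VEP.

    Variants are restricted to the two evaluation classes (ClinVar pathogenic
    = 1, gnomAD putatively benign = 0); scores are oriented so higher means
    more pathogenic.  Errors if either class vanishes globally; a region
    stratum losing a class only warns (that scope is skipped downstream).
    """
    if not scoresets:
        raise ValueError("need at least one retained VEP")
    eligible = variants.loc[
        variants["class_label"].isin(["clinvar_pathogenic", "gnomad_benign"])
    ].reset_index(drop=True)
    if "region" in eligible.columns:
        n_unassigned = int((eligible["region"] == "unassigned").sum())
        if n_unassigned:
            logger.info(
                "dropping %d unassigned-region variants from evaluation", n_unassigned
            )
            eligible = eligible.loc[eligible["region"] != "unassigned"].reset_index(drop=True)
    keys = variant_keys(eligible)
    keep = [i for i, k in enumerate(keys) if all(k in s.scores for s in scoresets)]
    kept = eligible.iloc[keep].reset_index(drop=True)
    kept_keys = [keys[i] for i in keep]
    kept = kept.assign(outcome=(kept["class_label"] == "clinvar_pathogenic").astype(int))

    outcome = kept["outcome"].to_numpy()
    if len(kept) == 0 or outcome.min() == outcome.max():
        raise ValueError("variant intersection left fewer than two outcome classes")
    for region in REGION_LABELS:
        sub = kept.loc[kept["region"] == region, "outcome"]
        if len(sub) == 0 or sub.nunique() < 2:
            logger.warning(
                "region %s lacks both outcome classes after intersection", region
            )

    oriented = {}
    for s in scoresets:
        col = np.array([s.scores[k] for k in kept_keys], dtype=float)
        oriented[s.name] = col if s.higher_is_pathogenic else -col
    scores = pd.DataFrame(oriented)
    for region in REGION_LABELS:
        n = int((kept["region"] == region).sum())
        n_path = int(kept.loc[kept["region"] == region, "outcome"].sum())
        logger.info("region %s: %d variants (%d pathogenic)", region, n, n_path)
    return EvaluationDataset(
        variants=kept, scores=scores, groups={s.name: s.group for s in scoresets}
    )


def orient_scores(scoreset: VepScoreSet, outcomes: dict[VariantKey, int] | None = None,
                  audit: bool = False) -> VepScoreSet:
    """Return a copy oriented so that higher score means more pathogenic.

    With ``audit`` set and outcomes supplied, computes AUROC on the shared
    variants and warns (never silently flips) when it falls below 0.5.
    """
    if scoreset.higher_is_pathogenic:
        out = replace(scoreset, scores=dict(scoreset.scores))
    else:
        out = replace(
            scoreset,
            higher_is_pathogenic=True,
            scores={k: -v for k, v in scoreset.scores.items()},
        )
    if audit and outcomes:
        shared = [k for k in out.scores if k in outcomes]
        y = [outcomes[k] for k in shared]
        if len(set(y)) == 2:
            a = auroc([out.scores[k] for k in shared], y)
            if a < 0.5:
                logger.warning(
                    "VEP %s: oriented AUROC %.3f < 0.5 — check higher_is_pathogenic",
                    out.name, a,
                )
    return out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def auroc(scores, outcomes) -> float:
    """AUROC by the rank (Mann-Whitney) formulation, ties counted one half.

    Equals the probability that a random pathogenic score exceeds a random
    benign score, and the trapezoidal area under the ROC curve.
    """
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be equal-length 1-D sequences")
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_curve(scores, outcomes) -> np.ndarray:
    """Vertex ROC curve: (FPR, TPR) points from (0,0) to (1,1), thresholds
    descending through the distinct observed scores (call rule score >= t)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    n1 = int(y.sum())
    n0 = len(y) - n1
    # cut after each distinct score value
    distinct_last = np.nonzero(np.diff(s) != 0)[0]
    cuts = np.concatenate([[0], distinct_last + 1, [len(s)]])
    tps = np.cumsum(y)
    tpr = np.concatenate([[0.0], tps[cuts[1:] - 1] / n1])
    fpr = np.concatenate([[0.0], (cuts[1:] - tps[cuts[1:] - 1]) / n0])
    return np.column_stack([fpr, tpr])


def confusion_at_threshold(scores, outcomes, threshold: float):
    """(sensitivity, specificity, counts) at the >=-threshold call rule.

    With no pathogenic variants in the subset sensitivity is NaN (flagged by
    the caller), mirroring for specificity.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    calls = s >= threshold
    tp = int(np.sum(calls & (y == 1)))
    fn = int(np.sum(~calls & (y == 1)))
    tn = int(np.sum(~calls & (y == 0)))
    fp = int(np.sum(calls & (y == 0)))
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    return sens, spec, {"tp": tp, "fp": fp, "tn": tn, "fn": fn}


def youden_threshold(scores, outcomes, vep: str = "", scope: str = "global") -> ThresholdResult:
    """Youden-J-optimal threshold over candidates = observed scores + +inf.

    J(t) = sensitivity(t) + specificity(t) - 1 under the >= call rule.  Ties
    on J are broken toward higher sensitivity, then the lower threshold —
    preferring not to miss pathogenic variants.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=int)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both outcome classes must be present")
    candidates = np.concatenate([np.unique(s), [np.inf]])
    # sens(t) = #{pos scores >= t}/n1; spec(t) = #{neg scores < t}/n0
    pos = np.sort(s[y == 1])
    neg = np.sort(s[y == 0])
    sens = (n1 - np.searchsorted(pos, candidates, side="left")) / n1
    spec = np.searchsorted(neg, candidates, side="left") / n0
    J = sens + spec - 1.0
    # lexicographic: max J, then max sens, then min threshold (candidates ascend,
    # so never updating on an exact tie keeps the lowest threshold)
    tol = 1e-12
    best = 0
    for i in range(1, len(candidates)):
        if J[i] > J[best] + tol or (J[i] > J[best] - tol and sens[i] > sens[best] + tol):
            best = i
    return ThresholdResult(
        vep=vep, scope=scope, threshold=float(candidates[best]), J=float(J[best]),
        sensitivity=float(sens[best]), specificity=float(spec[best]),
    )


def region_thresholds(dataset: EvaluationDataset, vep: str) -> list[ThresholdResult]:
    """Global plus per-region Youden thresholds for one VEP.

    Region scopes lacking either outcome class are skipped with a warning.
    """
    results = []
    s = dataset.scores[vep].to_numpy()
    y = dataset.outcomes
    for scope in SCOPES:
        mask = dataset.region_mask(scope)
        ys = y[mask]
        if len(ys) == 0 or ys.min() == ys.max():
            logger.warning("%s/%s: scope lacks both classes; skipped", vep, scope)
            continue
        results.append(youden_threshold(s[mask], ys, vep=vep, scope=scope))
    return results


def binarize(scores, threshold: float) -> np.ndarray:
    """Deterministic pathogenic calls: 1 iff score >= threshold."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def cohens_kappa(calls_a, calls_b) -> float:
    """Chance-corrected agreement between two binary call vectors.

    When expected agreement is 1 (both vectors constant) kappa is defined as
    1 for identical vectors and 0 otherwise.
    """
    a = np.asarray(calls_a, dtype=int)
    b = np.asarray(calls_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("call vectors must be equal-length non-empty 1-D sequences")
    n = a.size
    p_o = float(np.mean(a == b))
    p_e = 0.0
    for c in (0, 1):
        p_e += float(np.mean(a == c)) * float(np.mean(b == c))
    if p_e >= 1.0 - 1e-15:
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


def group_agreement(
    calls: dict[str, np.ndarray], groups: dict[str, str], scope: str = "global"
) -> list[KappaResult]:
    """Mean pairwise kappa within and between VEP groups.

    Each unordered VEP pair is counted once; SEM is the sample standard
    deviation over constituent pair kappas divided by sqrt(#pairs), matching
    error bars over pairs rather than variants.  Single-pair entries get
    SEM None (flagged); within-group entries need >= 2 members.
    """
    names = sorted(calls)
    pair_kappas: dict[tuple[str, str], list[float]] = {}
    for a, b in combinations(names, 2):
        ga, gb = sorted((groups[a], groups[b]))
        pair_kappas.setdefault((ga, gb), []).append(cohens_kappa(calls[a], calls[b]))
    present_groups = sorted({groups[n] for n in names})
    results = []
    for i, ga in enumerate(present_groups):
        for gb in present_groups[i:]:
            kappas = pair_kappas.get((ga, gb), [])
            if not kappas:
                if ga == gb:
                    logger.warning("group %s has < 2 members; within-group kappa skipped", ga)
                continue
            mean = float(np.mean(kappas))
            sem = (
                float(np.std(kappas, ddof=1) / math.sqrt(len(kappas)))
                if len(kappas) > 1 else None
            )
            results.append(KappaResult(scope, (ga, gb), mean, sem, len(kappas)))
    return results


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class VepBenchmark:
    """Region-stratified VEP benchmarking model.

    Built from region-assigned variants and raw score sets; ``fit()`` applies
    the coverage filter (VEPs first) and the variant intersection, then
    computes every metric, returning a :class:`VepBenchmarkResults`.

    Parameters
    ----------
    variants :
        Region-assigned variant table (from :mod:`idrbench.variants`),
        containing ClinVar-pathogenic and gnomAD-benign records.
    scoresets :
        Raw :class:`VepScoreSet` objects, unoriented.
    min_coverage :
        Minimum fraction of variants a VEP must score to be retained
        (inclusive).
    """

    def __init__(self, variants: pd.DataFrame, scoresets: list[VepScoreSet],
                 min_coverage: float = 0.75):
        if not 0 < min_coverage <= 1:
            raise ValueError("min_coverage must be in (0, 1]")
        self.variants = variants
        self.scoresets = scoresets
        self.min_coverage = min_coverage

    @classmethod
    def from_files(cls, variants_path, scores_path, metadata_path,
                   score_form: str = "long", **kwargs) -> "VepBenchmark":
        variants = pd.read_csv(variants_path, sep="\t", dtype={"protein_id": str})
        meta = load_vep_metadata(metadata_path)
        loader = {"long": load_scores_long, "wide": load_scores_wide}[score_form]
        return cls(variants, loader(scores_path, meta), **kwargs)

    def fit(self) -> "VepBenchmarkResults":
        retained, coverage = filter_by_coverage(
            self.scoresets, self.variants.loc[
                self.variants["class_label"].isin(["clinvar_pathogenic", "gnomad_benign"])
            ], self.min_coverage,
        )
        dataset = intersect_complete(self.variants, retained)

        metric_rows = []
        global_thresholds: dict[str, float] = {}
        for vep in dataset.vep_names:
            s = dataset.scores[vep].to_numpy()
            thresholds = {t.scope: t for t in region_thresholds(dataset, vep)}
            global_thresholds[vep] = thresholds["global"].threshold
            for scope in SCOPES:
                mask = dataset.region_mask(scope)
                ys = dataset.outcomes[mask]
                if scope not in thresholds:
                    continue
                t = thresholds[scope]
                au = auroc(s[mask], ys)
                # sens/spec at the global threshold within this scope (the
                # "one-threshold-fits-all" view the region thresholds improve on)
                g_sens, g_spec, counts = confusion_at_threshold(
                    s[mask], ys, global_thresholds[vep]
                )
                metric_rows.append({
                    "vep": vep, "group": dataset.groups[vep], "scope": scope,
                    "n": int(mask.sum()), "n_pathogenic": int(ys.sum()),
                    "auroc": au,
                    "threshold": t.threshold, "J": t.J,
                    "sensitivity": t.sensitivity, "specificity": t.specificity,
                    "sensitivity_at_global": g_sens, "specificity_at_global": g_spec,
                    "tp_at_global": counts["tp"], "fp_at_global": counts["fp"],
                    "tn_at_global": counts["tn"], "fn_at_global": counts["fn"],
                })

        # pairwise agreement at each VEP's global threshold
        calls = {
            vep: binarize(dataset.scores[vep].to_numpy(), global_thresholds[vep])
            for vep in dataset.vep_names
        }
        agreement_rows = []
        kappa_rows = []
        for scope in SCOPES:
            mask = dataset.region_mask(scope)
            if mask.sum() == 0:
                continue
            scoped = {v: c[mask] for v, c in calls.items()}
            for res in group_agreement(scoped, dataset.groups, scope):
                agreement_rows.append({
                    "scope": res.scope,
                    "group_pair": "|".join(res.group_pair),
                    "mean_kappa": res.mean_kappa,
                    "sem": res.sem, "n_pairs": res.n_pairs,
                })
            for a, b in combinations(sorted(scoped), 2):
                kappa_rows.append({
                    "scope": scope, "vep_a": a, "vep_b": b,
                    "kappa": cohens_kappa(scoped[a], scoped[b]),
                })

        return VepBenchmarkResults(
            dataset=dataset,
            coverage=coverage,
            metrics=pd.DataFrame(metric_rows),
            pair_kappas=pd.DataFrame(kappa_rows),
            agreement=pd.DataFrame(agreement_rows),
            global_thresholds=global_thresholds,
        )


@dataclass
class VepBenchmarkResults:
    """Fitted benchmark: per-VEP per-scope metrics and agreement tables.

    ``metrics`` has one row per (VEP, scope) with AUROC, the scope-specific
    Youden threshold and its sensitivity/specificity, plus the
    sensitivity/specificity the *global* threshold achieves in that scope.
    ``agreement`` summarises mean pairwise Cohen's kappa per group pair.
    """

    dataset: EvaluationDataset
    coverage: dict[str, float]
    metrics: pd.DataFrame
    pair_kappas: pd.DataFrame
    agreement: pd.DataFrame
    global_thresholds: dict[str, float]

    def auroc_table(self) -> pd.DataFrame:
        return self.metrics.pivot(index="vep", columns="scope", values="auroc")

    def threshold_table(self) -> pd.DataFrame:
        return self.metrics.pivot(index="vep", columns="scope", values="threshold")

    def summary(self) -> str:
        lines = ["VEP benchmark summary", "=" * 60]
        n = len(self.dataset.variants)
        n_path = int(self.dataset.outcomes.sum())
        lines.append(f"variants: {n} ({n_path} pathogenic, {n - n_path} benign)")
        counts = self.dataset.variants["region"].value_counts()
        lines.append(
            "regions: " + ", ".join(f"{r}={int(counts.get(r, 0))}" for r in REGION_LABELS)
        )
        lines.append(f"VEPs retained: {', '.join(self.dataset.vep_names)}")
        lines.append("")
        lines.append("AUROC by scope:")
        lines.append(self.auroc_table().round(3).to_string())
        lines.append("")
        lines.append("Youden thresholds by scope:")
        lines.append(self.threshold_table().round(3).to_string())
        lines.append("")
        lines.append("Sensitivity at global vs region-specific threshold:")
        piv = self.metrics.pivot(index="vep", columns="scope",
                                 values="sensitivity_at_global")
        lines.append(piv.round(3).to_string())
        if not self.agreement.empty:
            lines.append("")
            lines.append("Mean pairwise Cohen's kappa by group pair:")
            lines.append(self.agreement.round(3).to_string(index=False))
        return "\n".join(lines)

    def save(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(outdir / "vep_metrics.tsv", sep="\t", index=False)
        self.pair_kappas.to_csv(outdir / "kappa_pairs.tsv", sep="\t", index=False)
        self.agreement.to_csv(outdir / "group_agreement.tsv", sep="\t", index=False)
        cov = pd.DataFrame(
            {"vep": list(self.coverage), "coverage": list(self.coverage.values())}
        )
        cov.to_csv(outdir / "vep_coverage.tsv", sep="\t", index=False)
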