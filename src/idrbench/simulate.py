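"""Synthetic pLDDT profiles, variants and VEP scores with known ground truth.

The generator emulates the statistical structure the region-stratified
analysis assumes, so every pipeline stage can be exercised end-to-end with
no external downloads:

* **pLDDT profiles** — proteins as alternating ordered / disordered blocks;
  each residue's pLDDT is an independent truncated normal around the block
  state's mean (defaults: ordered 90 +/- 4, disordered 40 +/- 6).  Block
  structure supplies the long-range correlation that matters to the run-based
  classifier; within-block autocorrelation is deliberately not modelled.
  Ground truth labels each residue with its generating state, except that
  disordered blocks shorter than the 30-residue stretch minimum are truthed
  as intermediate (the classifier is *meant* to call them intermediate).

* **variants** — placed uniformly at random on residues of each structural
  region, with per-(region, class) expected counts drawn Poisson (or fixed).
  Defaults make pathogenic variants strongly depleted and putatively benign
  variants enriched in disordered regions.

* **VEP scores** — binormal per (region, class), with a per-variant shared
  latent factor so different VEPs agree more than chance.  The paper-like
  preset gives the disordered region an easy benign class (scores shifted
  far down) but a pathogenic class shifted toward benign, producing high
  disordered AUROC together with poor disordered sensitivity at a global
  threshold.

All randomness flows from a single seed through named
``numpy.random.SeedSequence`` substreams, so adding a generator never
perturbs existing outputs and identical inputs give byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .structure import (
    LABEL_DISORDERED,
    LABEL_INTERMEDIATE,
    LABEL_ORDERED,
    REGION_LABELS,
    PlddtProfile,
)

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Deterministic per-component substream of a single global seed."""
    digest = int.from_bytes(stream.encode(), "big") % (2**32)
    return np.random.default_rng(np.random.SeedSequence(entropy=(seed, digest)))


# ---------------------------------------------------------------------------
# pLDDT profiles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentModelParams:
    """Block model for synthetic pLDDT profiles.

    Emission defaults keep the two states well clear of the 50/70 decision
    thresholds so generator truth is recoverable.  Block-length ranges are
    inclusive; proteins alternate states starting from a random state.
    """

    n_proteins: int = 50
    ordered_len: tuple[int, int] = (60, 200)
    disordered_len: tuple[int, int] = (30, 90)
    intermediate_len: tuple[int, int] = (20, 60)
    ordered_mean: float = 90.0
    ordered_sd: float = 4.0
    disordered_mean: float = 40.0
    disordered_sd: float = 6.0
    intermediate_mean: float = 60.0
    intermediate_sd: float = 4.0
    p_intermediate: float = 0.3  # chance a low-confidence block is the milder kind
    min_blocks: int = 2
    max_blocks: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.disordered_mean < 50.0 <= 70.0 <= self.ordered_mean):
            raise ValueError(
                "defaults require disordered mean < 50 and ordered mean >= 70 "
                "so ground truth is recoverable"
            )
        if min(self.ordered_sd, self.disordered_sd, self.intermediate_sd) < 0:
            raise ValueError("emission standard deviations must be >= 0")
        if not 0 <= self.p_intermediate <= 1:
            raise ValueError("p_intermediate must be in [0, 1]")


def simulate_plddt_profiles(
    params: SegmentModelParams, stretch_min_len: int = 30
) -> tuple[list[PlddtProfile], pd.DataFrame]:
    """Generate block profiles plus per-residue ground-truth labels.

    Proteins alternate ordered and low-confidence blocks; a low-confidence
    block is disordered (mean ~40) or intermediate (mean ~60, still below the
    70 run cutoff but above the 50 disorder cutoff) with probability
    ``1 - p_intermediate`` / ``p_intermediate``.  Returns the profiles and a
    truth table (protein_id, position, label); disordered blocks shorter than
    ``stretch_min_len`` are truthed as intermediate.
    """
    rng = _rng(params.seed, "plddt")
    profiles = []
    truth_rows = []
    for p in range(params.n_proteins):
        protein_id = f"SYN{p + 1:04d}"
        n_blocks = int(rng.integers(params.min_blocks, params.max_blocks + 1))
        state = int(rng.integers(0, 2))  # 0 = ordered, 1 = low-confidence
        values = []
        labels = []
        for _ in range(n_blocks):
            if state == 0:
                lo, hi = params.ordered_len
                mean, sd = params.ordered_mean, params.ordered_sd
                truth = LABEL_ORDERED
            elif rng.random() < params.p_intermediate:
                lo, hi = params.intermediate_len
                mean, sd = params.intermediate_mean, params.intermediate_sd
                truth = LABEL_INTERMEDIATE
            else:
                lo, hi = params.disordered_len
                mean, sd = params.disordered_mean, params.disordered_sd
                truth = LABEL_DISORDERED
            length = int(rng.integers(lo, hi + 1))
            block = np.clip(rng.normal(mean, sd, size=length), 0.0, 100.0)
            if truth == LABEL_DISORDERED and length < stretch_min_len:
                truth = LABEL_INTERMEDIATE
            values.append(block)
            labels.extend([truth] * length)
            state = 1 - state
        plddt = np.concatenate(values)
        profiles.append(PlddtProfile(protein_id, plddt))
        truth_rows.append(
            pd.DataFrame(
                {
                    "protein_id": protein_id,
                    "position": np.arange(1, len(plddt) + 1),
                    "label": labels,
                }
            )
        )
    return profiles, pd.concat(truth_rows, ignore_index=True)


def profiles_to_frame(profiles: list[PlddtProfile]) -> pd.DataFrame:
    frames = [
        pd.DataFrame(
            {
                "protein_id": p.protein_id,
                "position": np.arange(1, p.length + 1),
                "plddt": np.round(p.plddt, 2),
            }
        )
        for p in profiles
    ]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantSimParams:
    """Expected variant counts per (class, region) plus label frequencies.

    ``class_region_counts`` maps class label -> expected counts over
    (disordered, intermediate, ordered).  Defaults: the pathogenic split
    mirrors the strong depletion of pathogenic variants in disorder
    (3.6% / 15.1% / 81.3% of 1500), while putatively benign population
    variants are enriched in disordered regions relative to that.

    ``ad_prob`` gives P(AD | region) for pathogenic variants (AD-gene
    variants are enriched in disorder relative to AR); ``mechanism_probs``
    gives (LOF, GOF, DN) frequencies per region for AD pathogenic variants.
    """

    class_region_counts: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            "clinvar_pathogenic": (54.0, 226.0, 1220.0),
            "gnomad_benign": (900.0, 600.0, 1500.0),
            "clinvar_benign": (60.0, 80.0, 260.0),
        }
    )
    ad_prob: dict[str, float] = field(
        default_factory=lambda: {
            LABEL_DISORDERED: 0.75,
            LABEL_INTERMEDIATE: 0.65,
            LABEL_ORDERED: 0.50,
        }
    )
    mechanism_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {
            LABEL_DISORDERED: (0.60, 0.30, 0.10),
            LABEL_INTERMEDIATE: (0.35, 0.45, 0.20),
            LABEL_ORDERED: (0.50, 0.20, 0.30),
        }
    )
    fixed_counts: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, rates in self.class_region_counts.items():
            if any(r < 0 for r in rates):
                raise ValueError(f"{cls}: rates must be >= 0")


def simulate_variants(
    params: VariantSimParams, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Place variants on annotated residues with region-dependent class rates.

    ``annotations`` is a residue table (protein_id, position, label).  Counts
    per (region, class) are Poisson around the expected counts (exactly equal
    in ``fixed_counts`` mode); residues are drawn uniformly with replacement
    within each region; ref/alt amino acids are uniform over distinct
    letters.  Regions with a positive rate but no annotated residues are
    skipped with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    rng = _rng(params.seed, "variants")
    by_region = {
        region: annotations.loc[annotations["label"] == region]
        for region in REGION_LABELS
    }
    rows = []
    for cls, rates in params.class_region_counts.items():
        for region, rate in zip(REGION_LABELS, rates):
            if rate == 0:
                continue
            pool = by_region[region]
            if pool.empty:
                logger.warning(
                    "no %s residues available; ignoring rate for class %s", region, cls
                )
                continue
            n = int(round(rate)) if params.fixed_counts else int(rng.poisson(rate))
            if n == 0:
                continue
            idx = rng.integers(0, len(pool), size=n)
            picked = pool.iloc[idx]
            ref_idx = rng.integers(0, 20, size=n)
            alt_idx = (ref_idx + rng.integers(1, 20, size=n)) % 20
            inheritance = np.full(n, "unknown", dtype=object)
            mechanism = np.full(n, "unknown", dtype=object)
            if cls == "clinvar_pathogenic":
                is_ad = rng.random(n) < params.ad_prob[region]
                inheritance = np.where(is_ad, "AD", "AR")
                mech_draw = rng.choice(
                    ["LOF", "GOF", "DN"], size=n, p=params.mechanism_probs[region]
                )
                # AR disease variants act almost exclusively via loss of function
                mechanism = np.where(is_ad, mech_draw, "LOF")
            rows.append(
                pd.DataFrame(
                    {
                        "protein_id": picked["protein_id"].to_numpy(),
                        "gene": [f"G{pid[3:]}" for pid in picked["protein_id"]],
                        "position": picked["position"].to_numpy(),
                        "ref_aa": AMINO_ACIDS[ref_idx],
                        "alt_aa": AMINO_ACIDS[alt_idx],
                        "class_label": cls,
                        "inheritance": inheritance,
                        "mechanism": mechanism,
                        "region": region,
                    }
                )
            )
    if not rows:
        raise ValueError("no variants generated; check rates and annotations")
    # duplicate (protein, position, alt, class) keys can occur at high variant
    # density; deduplication is the loader's contract, not the generator's
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# VEP scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VepSimSpec:
    """Binormal score model for one simulated predictor.

    ``region_params`` maps region -> (mu_benign, mu_path, sd_benign, sd_path)
    on the oriented (higher = pathogenic) scale; emitted scores are negated
    when ``higher_is_pathogenic`` is False.
    """

    name: str
    group: str
    higher_is_pathogenic: bool = True
    region_params: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: {
            LABEL_DISORDERED: (-1.5, 0.8, 0.6, 1.0),
            LABEL_INTERMEDIATE: (-0.5, 1.6, 0.9, 1.0),
            LABEL_ORDERED: (0.0, 2.0, 1.0, 1.0),
        }
    )
    missingness: float = 0.0

    def __post_init__(self) -> None:
        for region, (mb, mp, sb, sp) in self.region_params.items():
            if sb <= 0 or sp <= 0:
                raise ValueError(f"{self.name}/{region}: standard deviations must be > 0")
        if not 0 <= self.missingness < 1:
            raise ValueError("missingness must be in [0, 1)")


@dataclass(frozen=True)
class ScoreSimParams:
    veps: tuple[VepSimSpec, ...]
    latent_rho: float = 0.7  # shared per-variant factor -> inter-VEP agreement
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 < self.latent_rho < 1.0:
            raise ValueError("latent_rho must be in (-1, 1)")


def simulate_vep_scores(params: ScoreSimParams, variants: pd.DataFrame):
    """Draw binormal scores for every variant and VEP.

    score = mu(region, class) + sd * (rho * z_variant + sqrt(1 - rho^2) * eps),
    with a per-variant latent ``z`` shared across VEPs.  Missingness drops
    variants independently per VEP at the configured rate.  Returns
    :class:`idrbench.vep.VepScoreSet` objects.
    """
    from .vep import VepScoreSet

    rng = _rng(params.seed, "scores")
    n = len(variants)
    latent = rng.standard_normal(n)
    is_path = (variants["class_label"] == "clinvar_pathogenic").to_numpy()
    regions = variants["region"].to_numpy()
    keys = list(
        zip(
            variants["protein_id"],
            variants["position"].astype(int),
            variants["ref_aa"],
            variants["alt_aa"],
        )
    )
    rho = params.latent_rho
    scoresets = []
    for spec in params.veps:
        eps = rng.standard_normal(n)
        mu = np.empty(n)
        sd = np.empty(n)
        for region, (mb, mp, sb, sp) in spec.region_params.items():
            mask = regions == region
            mu[mask] = np.where(is_path[mask], mp, mb)
            sd[mask] = np.where(is_path[mask], sp, sb)
        scores = mu + sd * (rho * latent + math.sqrt(1 - rho**2) * eps)
        if not spec.higher_is_pathogenic:
            scores = -scores
        present = rng.random(n) >= spec.missingness
        scoresets.append(
            VepScoreSet(
                name=spec.name,
                group=spec.group,
                higher_is_pathogenic=spec.higher_is_pathogenic,
                scores={k: float(s) for k, s, keep in zip(keys, scores, present) if keep},
            )
        )
    return scoresets


def expected_auroc(mu_path: float, mu_ben: float, sd_path: float, sd_ben: float) -> float:
    """Closed-form binormal AUROC: Phi((mu_path - mu_ben) / sqrt(sp^2 + sb^2))."""
    if sd_path <= 0 or sd_ben <= 0:
        raise ValueError("standard deviations must be > 0")
    return float(norm.cdf((mu_path - mu_ben) / math.hypot(sd_path, sd_ben)))


# ---------------------------------------------------------------------------
# presets
# ---------------------------------------------------------------------------

def _preset_veps(preset: str) -> tuple[VepSimSpec, ...]:
    paper_like = VepSimSpec("", "").region_params
    flat = {r: (0.0, 2.0, 1.0, 1.0) for r in REGION_LABELS}
    null = {r: (0.0, 0.0, 1.0, 1.0) for r in REGION_LABELS}
    region_params = {"paper-like": paper_like, "separable": flat, "null": null}[preset]

    def shifted(delta: float):
        return {r: (mb + delta, mp + delta, sb, sp)
                for r, (mb, mp, sb, sp) in region_params.items()}

    return (
        VepSimSpec("clintraindA", "clinical_trained", True, shifted(0.0)),
        VepSimSpec("clintraindB", "clinical_trained", True, shifted(0.2)),
        VepSimSpec("poptunedA", "population_tuned", True, shifted(-0.1)),
        VepSimSpec("popfreeA", "population_free", True, shifted(0.1)),
        VepSimSpec("popfreeB", "population_free", False, shifted(0.0)),
        VepSimSpec("popfreeC", "population_free", True, shifted(0.0), missingness=0.3),
    )


def simulate_preset(preset: str, seed: int, outdir,
                    n_proteins: int = 50) -> dict[str, Path]:
    """Write a complete synthetic input bundle for the pipeline.

    Produces the same TSV formats the pipeline consumes: pLDDT table, variant
    table, long-form score table, VEP metadata YAML, and a small gene
    exclusion list (a few genes flagged as collagen-like so the exclusion
    stage is exercised).
    """
    if preset not in ("paper-like", "null", "separable"):
        raise ValueError(f"unknown preset {preset!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seg = SegmentModelParams(n_proteins=n_proteins, seed=seed)
    profiles, truth = simulate_plddt_profiles(seg)
    plddt_path = outdir / "plddt.tsv"
    profiles_to_frame(profiles).to_csv(plddt_path, sep="\t", index=False)

    var_params = VariantSimParams(seed=seed)
    variants = simulate_variants(var_params, truth)
    # flag ~2% of genes as collagen-like for the exclusion stage
    genes = sorted(variants["gene"].unique())
    excl_rng = _rng(seed, "exclusion")
    n_excl = max(1, len(genes) // 50)
    excluded = sorted(excl_rng.choice(genes, size=n_excl, replace=False))
    excl_path = outdir / "collagen_genes.txt"
    excl_path.write_text("".join(g + "\n" for g in excluded))

    variants_path = outdir / "variants.tsv"
    variants.drop(columns=["region"]).to_csv(variants_path, sep="\t", index=False)

    score_params = ScoreSimParams(veps=_preset_veps(preset), seed=seed)
    scoresets = simulate_vep_scores(score_params, variants)
    rows = []
    for s in scoresets:
        for (pid, pos, ref, alt), score in s.scores.items():
            rows.append((s.name, pid, pos, ref, alt, round(score, 6)))
    scores_path = outdir / "vep_scores.tsv"
    pd.DataFrame(
        rows, columns=["vep", "protein_id", "position", "ref_aa", "alt_aa", "score"]
    ).to_csv(scores_path, sep="\t", index=False)

    meta = {
        s.name: {"group": s.group, "higher_is_pathogenic": s.higher_is_pathogenic}
        for s in scoresets
    }
    meta_path = outdir / "vep_metadata.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)

    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(
            {
                "inputs": {
                    "plddt": str(plddt_path),
                    "variants": str(variants_path),
                    "scores": str(scores_path),
                    "vep_metadata": str(meta_path),
                    "exclusion_list": str(excl_path),
                },
                "outdir": str(outdir / "out"),
                "seed": seed,
            },
            fh, sort_keys=True,
        )

    return {
        "plddt": plddt_path,
        "variants": variants_path,
        "scores": scores_path,
        "metadata": meta_path,
        "exclusion": excl_path,
        "config": config_path,
    }
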