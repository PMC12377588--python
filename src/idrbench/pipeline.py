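"""End-to-end orchestration: classify -> assign -> statistics -> evaluate.

A single declarative config (YAML mapping or plain dict) drives the run.
Every numeric constant of the analysis is a named parameter with its
conventional value as default — the pLDDT thresholds (50 / 30 / 70 / 70),
the 75% VEP coverage requirement, the 95% CI level and the 30%
highly-disordered cutoff — nothing is hard-coded in the stages.

Outputs are plain TSV/JSON files plus a machine-readable run report whose
counts let the filtering narrative be audited (how many variants the
collagen exclusion removed, how many lacked pLDDT coverage, how many
survived the score intersection).
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .structure import (
    ClassifierParams,
    annotations_to_frame,
    classify_residues,
    find_low_confidence_stretches,
    read_plddt_table,
    summarize_protein,
    summarize_proteome,
    write_annotations,
    write_proteome_summary,
    write_segments,
)
from .variants import (
    assign_regions,
    binomial_ci,
    exclude_genes,
    fisher_exact_2x2,
    load_exclusion_list,
    load_variants,
    region_distribution,
)
from .vep import VepBenchmark, load_scores_long, load_scores_wide, load_vep_metadata

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "inputs": {
        "plddt": None,
        "variants": None,
        "scores": None,
        "score_form": "long",
        "vep_metadata": None,
        "exclusion_list": None,
    },
    "classifier": {
        "disorder_plddt_max": 50.0,
        "stretch_min_len": 30,
        "stretch_mean_max": 70.0,
        "ordered_plddt_min": 70.0,
        "stretch_mode": "maximal_run",
    },
    "analysis": {
        "min_coverage": 0.75,
        "ci_level": 0.95,
        "highly_disordered_min": 0.30,
        "strata": ["class_label", "inheritance", "mechanism"],
        "strict_assignment": False,
    },
    "outdir": None,
    "seed": 0,
    "log_level": "INFO",
}

_RANGES = {
    ("classifier", "disorder_plddt_max"): (0.0, 100.0),
    ("classifier", "stretch_mean_max"): (0.0, 100.0),
    ("classifier", "ordered_plddt_min"): (1e-9, 100.0),
    ("analysis", "min_coverage"): (1e-9, 1.0),
    ("analysis", "ci_level"): (1e-9, 1.0 - 1e-9),
    ("analysis", "highly_disordered_min"): (0.0, 1.0),
}


def validate_config(config: dict) -> dict:
    """Inject defaults, reject unknown keys, and range-check parameters."""
    out = copy.deepcopy(DEFAULT_CONFIG)
    for section, value in config.items():
        if section not in out:
            raise ValueError(f"unknown config key {section!r}")
        if isinstance(out[section], dict):
            if not isinstance(value, dict):
                raise ValueError(f"config section {section!r} must be a mapping")
            for key, v in value.items():
                if key not in out[section]:
                    raise ValueError(f"unknown config key {section}.{key}")
                out[section][key] = v
        else:
            out[section] = value

    for (section, key), (lo, hi) in _RANGES.items():
        v = out[section][key]
        if not isinstance(v, (int, float)) or not lo <= v <= hi:
            raise ValueError(f"{section}.{key} = {v!r} out of range [{lo}, {hi}]")
    if not isinstance(out["classifier"]["stretch_min_len"], int) or \
            out["classifier"]["stretch_min_len"] < 1:
        raise ValueError("classifier.stretch_min_len must be an integer >= 1")
    # constructing the params object enforces the remaining invariants
    ClassifierParams(**out["classifier"])
    if out["inputs"]["score_form"] not in ("long", "wide"):
        raise ValueError("inputs.score_form must be 'long' or 'wide'")
    if out["outdir"] is None:
        raise ValueError("outdir is required")
    for key in ("plddt", "variants"):
        path = out["inputs"][key]
        if path is not None and not Path(path).exists():
            raise ValueError(f"inputs.{key}: file not found: {path}")
    for key in ("scores", "vep_metadata", "exclusion_list"):
        path = out["inputs"][key]
        if path is not None and not Path(path).exists():
            raise ValueError(f"inputs.{key}: file not found: {path}")
    return out


def load_config(path) -> dict:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return validate_config(raw)


def _fingerprint(path) -> dict:
    data = Path(path).read_bytes()
    return {
        "path": str(path),
        "sha256": hashlib.sha256(data).hexdigest(),
        "bytes": len(data),
    }


def run_all(config: dict, stages: tuple[str, ...] = ("classify", "variants", "evaluate")) -> dict:
    """Execute the pipeline stages and return the run report (also written
    to ``<outdir>/run_report.json``).

    Stages may be restricted; later stages read the earlier stages' output
    files from ``outdir``, so running them one at a time is equivalent to a
    single ``run_all``.
    """
    config = validate_config(config)
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "parameters": {k: config[k] for k in ("classifier", "analysis", "seed")},
        "inputs": {},
        "counts": {},
    }
    for key, path in config["inputs"].items():
        if key != "score_form" and path is not None:
            report["inputs"][key] = _fingerprint(path)

    cls_params = ClassifierParams(**config["classifier"])

    if "classify" in stages:
        _stage_classify(config, cls_params, outdir, report)
    if "variants" in stages:
        _stage_variants(config, outdir, report)
    if "evaluate" in stages and config["inputs"]["scores"] is not None:
        _stage_evaluate(config, outdir, report)

    with open(outdir / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
        fh.write("\n")
    return report


def _stage_classify(config, cls_params, outdir: Path, report: dict) -> None:
    if config["inputs"]["plddt"] is None:
        raise ValueError("classify stage requires inputs.plddt")
    profiles = read_plddt_table(config["inputs"]["plddt"])
    annotations = []
    segments = []
    summaries = []
    for profile in profiles:
        anns = classify_residues(profile, cls_params)
        annotations.extend(anns)
        segments.extend(find_low_confidence_stretches(profile, cls_params))
        summaries.append(summarize_protein(anns))
    write_annotations(annotations, outdir / "residue_annotations.tsv")
    write_segments(segments, outdir / "disorder_segments.tsv")
    proteome = summarize_proteome(summaries)
    write_proteome_summary(proteome, outdir / "proteome_summary.json")
    report["counts"]["proteins"] = len(profiles)
    report["counts"]["residues"] = proteome.n_residues
    report["counts"]["disorder_segments"] = len(segments)
    report["proteome"] = proteome.__dict__


def _stage_variants(config, outdir: Path, report: dict) -> None:
    if config["inputs"]["variants"] is None:
        raise ValueError("variants stage requires inputs.variants")
    df = load_variants(config["inputs"]["variants"])
    n_loaded = len(df)

    if config["inputs"]["exclusion_list"] is not None:
        exclusion = load_exclusion_list(config["inputs"]["exclusion_list"])
        df, excl_report = exclude_genes(df, exclusion)
    else:
        excl_report = {"removed_total": 0, "removed_per_class": {}}

    annotations = pd.read_csv(outdir / "residue_annotations.tsv", sep="\t",
                              dtype={"protein_id": str})
    df, assign_report = assign_regions(
        df, annotations, strict=config["analysis"]["strict_assignment"]
    )
    df.to_csv(outdir / "variants_assigned.tsv", sep="\t", index=False)

    dists = []
    dists.append(region_distribution(df, ["class_label"]))
    for stratum in config["analysis"]["strata"]:
        if stratum != "class_label":
            dists.append(
                region_distribution(
                    df.loc[df["class_label"] == "clinvar_pathogenic"],
                    ["class_label", stratum],
                )
            )
    pd.concat(dists, ignore_index=True).to_csv(
        outdir / "region_distributions.tsv", sep="\t", index=False
    )

    enrichment = _enrichment_stats(df, config["analysis"]["ci_level"])
    with open(outdir / "enrichment.json", "w") as fh:
        json.dump(enrichment, fh, indent=2)
        fh.write("\n")

    report["counts"].update(
        {
            "variants_loaded": n_loaded,
            "variants_excluded_collagen": excl_report["removed_total"],
            "variants_unassigned": assign_report["n_unassigned"],
            "variants_assigned": assign_report["n_assigned"],
        }
    )
    report["collagen_exclusion"] = excl_report


def _enrichment_stats(df: pd.DataFrame, ci_level: float) -> dict:
    """AD-vs-AR disorder enrichment (Fisher) and per-mechanism binomial CIs."""
    out: dict = {}
    path = df.loc[
        (df["class_label"] == "clinvar_pathogenic") & (df["region"] != "unassigned")
    ]
    for region in ("disordered", "intermediate"):
        ad = path.loc[path["inheritance"] == "AD"]
        ar = path.loc[path["inheritance"] == "AR"]
        if len(ad) and len(ar):
            table = [
                [int((ad["region"] == region).sum()), int((ad["region"] != region).sum())],
                [int((ar["region"] == region).sum()), int((ar["region"] != region).sum())],
            ]
            res = fisher_exact_2x2(table)
            out[f"ad_vs_ar_{region}"] = {
                "table": table,
                "proportion_ad": table[0][0] / len(ad),
                "proportion_ar": table[1][0] / len(ar),
                "odds_ratio": res.odds_ratio,
                "p_value": res.p_value,
            }
    mech_ci = {}
    ad_path = path.loc[path["inheritance"] == "AD"]
    for mech in ("LOF", "GOF", "DN"):
        sub = ad_path.loc[ad_path["mechanism"] == mech]
        if len(sub) == 0:
            continue
        per_region = {}
        for region in ("disordered", "intermediate", "ordered"):
            k = int((sub["region"] == region).sum())
            ci = binomial_ci(k, len(sub), level=ci_level)
            per_region[region] = {
                "k": k, "n": ci.n, "proportion": ci.point,
                "ci_lower": ci.lower, "ci_upper": ci.upper,
            }
        mech_ci[mech] = per_region
    out["mechanism_binomial_ci"] = mech_ci
    return out


def _stage_evaluate(config, outdir: Path, report: dict) -> None:
    for key in ("scores", "vep_metadata"):
        if config["inputs"][key] is None:
            raise ValueError(f"evaluate stage requires inputs.{key}")
    variants = pd.read_csv(outdir / "variants_assigned.tsv", sep="\t",
                           dtype={"protein_id": str})
    meta = load_vep_metadata(config["inputs"]["vep_metadata"])
    loader = {"long": load_scores_long, "wide": load_scores_wide}[
        config["inputs"]["score_form"]
    ]
    scoresets = loader(config["inputs"]["scores"], meta)
    model = VepBenchmark(variants, scoresets,
                         min_coverage=config["analysis"]["min_coverage"])
    results = model.fit()
    results.save(outdir)
    (outdir / "benchmark_summary.txt").write_text(results.summary() + "\n")

    n_assigned_eval = int(
        (
            variants["class_label"].isin(["clinvar_pathogenic", "gnomad_benign"])
            & (variants["region"] != "unassigned")
        ).sum()
    )
    retained = len(results.dataset.variants)
    report["counts"].update(
        {
            "veps_supplied": len(scoresets),
            "veps_retained": len(results.dataset.vep_names),
            "variants_evaluation_classes": n_assigned_eval,
            "variants_dropped_by_intersection": n_assigned_eval - retained,
            "variants_retained_evaluation": retained,
        }
    )
    report["vep_coverage"] = results.coverage
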