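"""End-to-end orchestration: impute -> score -> classify -> genomics -> comparisons.

A run is a pure function of (config, inputs, seed): identical configs and
inputs produce byte-identical output tables and result JSONs (no timestamps
in any result file). Every threshold actually used (median cutoffs, probe
exclusions) is logged and written into the provenance record so the
classification is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    Thresholds,
    assign_subgroups,
    classify_ki67_response,
    classify_pathological_response,
    read_clinical_csv,
    thresholds_from_scores,
)
from .genomics import (
    compute_tmb,
    frequency_table_and_test,
    load_default_exclusion,
    read_maf,
    top_mutated_genes,
)
from .matrix import ExpressionMatrix, impute_missing, read_expression_tsv
from .signatures import (
    filter_discordant_probes,
    load_mks_ers,
    read_gmt,
    resolve_features,
    score_metagene,
    score_panel,
)
from .stats import (
    ContingencyTable2x2,
    cox_univariate,
    km_estimate,
    logrank_test,
    midp_median_unbiased_or,
)

log = logging.getLogger("mksers")

_KNOWN_KEYS = {
    "expression", "clinical", "mutations", "panel_gmt", "platform", "linear_scale",
    "mode", "thresholds", "alpha", "top_k_genes", "exclusion_file", "comparisons",
    "out_dir", "seed", "log_level",
}


@dataclass
class RunConfig:
    """Validated pipeline configuration (unknown keys rejected)."""

    expression: str
    clinical: str | None = None
    mutations: str | None = None
    panel_gmt: str | None = None
    platform: str = "generic"
    linear_scale: bool = False
    mode: str = "four_group"  # four_group | ers_only
    thresholds: dict | None = None  # {"mks_cut": x, "ers_cut": y} -> predefined
    alpha: float = 0.05
    top_k_genes: int = 15
    exclusion_file: str | None = None
    comparisons: list[dict] = field(default_factory=list)
    out_dir: str = "mksers_out"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "expression" not in raw:
            raise ValueError("config must set 'expression'")
        return cls(**raw)

    _PATH_KEYS = ("expression", "clinical", "mutations", "panel_gmt", "exclusion_file")

    def canonical_hash(self) -> str:
        """Hash of the analysis-relevant configuration plus input contents.

        Input files enter by content, not by path, and the output location is
        excluded, so the same inputs and settings hash identically wherever
        they live.
        """
        payload = {k: v for k, v in self.__dict__.items()
                   if k not in {"out_dir", "log_level", *self._PATH_KEYS}}
        h = hashlib.sha256(json.dumps(payload, sort_keys=True, default=str).encode())
        for key in self._PATH_KEYS:
            path = getattr(self, key)
            if path:
                h.update(key.encode())
                h.update(Path(path).read_bytes())
        return h.hexdigest()[:16]


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def score_and_classify(
    matrix: ExpressionMatrix,
    mode: str = "four_group",
    thresholds: Thresholds | None = None,
    panel=None,
) -> tuple[pd.DataFrame, Thresholds, dict]:
    """Impute, score MKS/ERS (+ optional panel), and assign subgroup labels.

    Returns (labels frame, thresholds used, audit dict of filtering decisions).
    """
    audit: dict = {}
    matrix = impute_missing(matrix)
    sigs = load_mks_ers()
    scores = {}
    for name in ("MKS", "ERS"):
        feats = resolve_features(sigs[name], matrix)
        if not matrix.is_affymetrix and len(feats) > len(set(sigs[name].symbols)):
            kept = filter_discordant_probes(matrix, feats)
            audit[f"{name}_probes_excluded"] = sorted(set(feats) - set(kept))
            feats = kept
        audit[f"{name}_features"] = feats
        scores[name] = score_metagene(matrix, sigs[name], feats)
    if thresholds is None:
        thresholds = thresholds_from_scores(scores["MKS"], scores["ERS"])
    audit["thresholds"] = {"mks_cut": thresholds.mks_cut, "ers_cut": thresholds.ers_cut,
                           "source": thresholds.source}
    labels = assign_subgroups(scores["MKS"], scores["ERS"], thresholds, mode=mode)
    out = pd.DataFrame({
        "sample_id": matrix.sample_ids,
        "mks_score": scores["MKS"],
        "ers_score": scores["ERS"],
        "subgroup": labels,
        "mks_cut": thresholds.mks_cut,
        "ers_cut": thresholds.ers_cut,
        "threshold_source": thresholds.source,
    })
    if panel:
        table = score_panel(matrix, panel)
        for name, vec in table.scores.items():
            out[f"panel_{name}"] = vec
        audit["panel_n_features_used"] = table.n_features_used
        audit["panel_unrepresented"] = table.unrepresented
    return out, thresholds, audit


def _response_comparison(merged: pd.DataFrame, spec: dict, alpha: float) -> dict:
    endpoint = spec["endpoint"]  # pcr | pathr
    groups = spec.get("groups")  # two subgroup labels, or use arm within stratum
    coded = merged["rcb_class"].map(classify_pathological_response)
    merged = merged.assign(
        response=[(flag if endpoint == "pcr" else (grp == "pathR")) if grp is not None
                  else None for grp, flag in coded]
    )
    if groups:
        sel = merged[merged["subgroup"].isin(groups)].dropna(subset=["response"])
        exposed = sel["subgroup"] == groups[0]
    else:  # arm comparison within a subgroup stratum
        sel = merged[merged["subgroup"] == spec["stratum"]].dropna(subset=["response"])
        exposed = sel["arm"] == spec["exposed_arm"]
    resp = sel["response"].astype(bool)
    table = ContingencyTable2x2(
        a=int((resp & exposed).sum()), b=int((~resp & exposed).sum()),
        c=int((resp & ~exposed).sum()), d=int((~resp & ~exposed).sum()),
    )
    res = midp_median_unbiased_or(table, alpha=alpha)
    return {
        "type": "response", "endpoint": endpoint,
        "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "n_exposed": table.a + table.b, "n_unexposed": table.c + table.d,
        "rate_exposed": table.a / max(table.a + table.b, 1),
        "rate_unexposed": table.c / max(table.c + table.d, 1),
        "odds_ratio": res.psi_hat, "ci_low": res.ci_low, "ci_high": res.ci_high,
        "alpha": res.alpha, "method": res.method,
    }


def _survival_comparison(merged: pd.DataFrame, spec: dict, alpha: float) -> dict:
    groups = spec["groups"]
    sel = merged[merged["subgroup"].isin(groups)].dropna(subset=["time_years", "event"])
    times = sel["time_years"].to_numpy(float)
    events = sel["event"].astype(bool).to_numpy()
    labels = sel["subgroup"].to_numpy()
    stat, df, p = logrank_test(times, events, labels)
    out = {"type": "survival", "groups": list(groups),
           "n": {g: int((labels == g).sum()) for g in groups},
           "logrank_chi2": stat, "df": df, "logrank_p": p}
    horizon = spec.get("horizon_years")
    if horizon is not None:
        out["survival_at_horizon"] = {
            g: km_estimate(times[labels == g], events[labels == g]).survival_at(float(horizon))
            for g in groups
        }
    if len(groups) == 2:
        cox = cox_univariate(times, events, (labels == groups[0]).astype(float), alpha=alpha)
        out.update({"hr": cox.hr, "hr_ci_low": cox.ci_low, "hr_ci_high": cox.ci_high,
                    "cox_p": cox.p_value, "cox_flagged": cox.flagged})
    return out


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all stages and write the result bundle under cfg.out_dir."""
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    try:
        matrix = read_expression_tsv(cfg.expression, platform=cfg.platform,
                                     linear_scale=cfg.linear_scale)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'load_expression' failed: {exc}") from exc

    panel = read_gmt(cfg.panel_gmt) if cfg.panel_gmt else None
    thresholds = None
    if cfg.thresholds:
        thresholds = Thresholds(float(cfg.thresholds["mks_cut"]),
                                float(cfg.thresholds["ers_cut"]), source="predefined")
    try:
        labels_df, thresholds, audit = score_and_classify(
            matrix, mode=cfg.mode, thresholds=thresholds, panel=panel)
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'score_classify' failed: {exc}") from exc
    log.info("thresholds used: %s", audit["thresholds"])
    labels_df.to_csv(out / "labels.tsv", sep="\t", index=False)

    merged = labels_df
    if cfg.clinical:
        clinical = read_clinical_csv(cfg.clinical)
        merged = labels_df.merge(clinical, on="sample_id", how="left")
        if "ki67_post_pct" in merged.columns:
            merged["ki67_response"] = merged["ki67_post_pct"].map(classify_ki67_response)

    results: dict = {"comparisons": {}}
    if cfg.mutations:
        try:
            muts = read_maf(cfg.mutations)
            tmb = compute_tmb(muts, labels_df["sample_id"].tolist())
            tmb.to_csv(out / "tmb.tsv", sep="\t", header=True)
            exclusion = (load_default_exclusion() if cfg.exclusion_file is None
                         else [ln.strip() for ln in Path(cfg.exclusion_file).read_text()
                               .splitlines() if ln.strip() and not ln.startswith("#")])
            genes = top_mutated_genes(muts, labels_df["sample_id"].tolist(),
                                      k=cfg.top_k_genes, exclusion=exclusion)
            lbl = pd.Series(labels_df["subgroup"].to_numpy(),
                            index=labels_df["sample_id"]).dropna()
            freq = frequency_table_and_test(muts, lbl, genes)
            freq.to_csv(out / "gene_frequency.tsv", sep="\t")
            results["tmb_median_by_subgroup"] = {
                g: float(tmb[labels_df.loc[labels_df["subgroup"] == g, "sample_id"]].median())
                for g in pd.unique(labels_df["subgroup"].dropna())
            }
            results["top_mutated_genes"] = genes
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'genomics' failed: {exc}") from exc

    for spec in cfg.comparisons:
        name = spec.get("name") or f"{spec['endpoint']}_{'_'.join(spec.get('groups', []))}"
        try:
            if spec["endpoint"] in {"pcr", "pathr"}:
                results["comparisons"][name] = _response_comparison(merged, spec, cfg.alpha)
            elif spec["endpoint"] in {"defs", "os", "survival"}:
                results["comparisons"][name] = _survival_comparison(merged, spec, cfg.alpha)
            else:
                raise ValueError(f"unknown endpoint {spec['endpoint']!r}")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"stage 'comparison:{name}' failed: {exc}") from exc

    results["provenance"] = {
        "config_hash": cfg.canonical_hash(),
        "seed": cfg.seed,
        "version": __version__,
        "thresholds": audit["thresholds"],
        "audit": {k: v for k, v in audit.items() if k != "thresholds"},
    }
    (out / "results.json").write_text(
        json.dumps(results, indent=2, sort_keys=True, default=_json_default) + "\n")
    return results
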