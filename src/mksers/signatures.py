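"""Gene signatures: resolution to matrix features, probe filtering, scoring.

A metagene score is the (weighted) arithmetic mean of log-scale expression over
the signature's features. On Affymetrix platforms the shipped MKS/ERS
signature resolves through its probe-set IDs; on every other platform it
resolves by gene symbol (case-insensitive), and when a gene maps to several
features the discordant ones are removed by correlation clustering before
averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .matrix import ExpressionMatrix

__all__ = [
    "GeneSignature",
    "SignatureMember",
    "ScoreTable",
    "SignatureUnrepresentedError",
    "read_gmt",
    "write_gmt",
    "load_mks_ers",
    "load_default_panel",
    "resolve_features",
    "filter_discordant_probes",
    "score_metagene",
    "score_panel",
]

DEFAULT_PROBE_R_MIN = 0.4


class SignatureUnrepresentedError(KeyError):
    """No feature of the matrix matches the signature."""


@dataclass(frozen=True)
class SignatureMember:
    symbol: str
    probe_id: str | None = None
    weight: float = 1.0


@dataclass
class GeneSignature:
    """Named gene list with optional probe-set IDs and per-gene weights."""

    name: str
    members: list[SignatureMember]
    aggregation: str = "mean"  # mean | weighted_mean | single_gene

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"signature {self.name!r} has no members")
        if not all(np.isfinite(m.weight) for m in self.members):
            raise ValueError(f"signature {self.name!r} has non-finite weights")
        if self.aggregation == "single_gene" and len(self.members) != 1:
            raise ValueError("single_gene signatures must have exactly one member")
        if self.aggregation not in {"mean", "weighted_mean", "single_gene"}:
            raise ValueError(f"unknown aggregation {self.aggregation!r}")

    @property
    def symbols(self) -> list[str]:
        return [m.symbol for m in self.members]

    @property
    def has_probes(self) -> bool:
        return all(m.probe_id is not None for m in self.members)


@dataclass
class ScoreTable:
    """Per-sample signature scores plus the feature count each score used."""

    sample_ids: list[str]
    scores: dict[str, np.ndarray] = field(default_factory=dict)
    n_features_used: dict[str, int] = field(default_factory=dict)
    unrepresented: list[str] = field(default_factory=list)

    def add(self, name: str, values: np.ndarray, n_features: int) -> None:
        if len(values) != len(self.sample_ids):
            raise ValueError("score vector length does not match sample count")
        if n_features < 1:
            raise ValueError("a reported signature must use at least one feature")
        self.scores[name] = np.asarray(values, dtype=float)
        self.n_features_used[name] = int(n_features)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=pd.Index(self.sample_ids, name="sample_id"))


# ---------------------------------------------------------------------------
# GMT I/O
#
# Member syntax: SYMBOL, SYMBOL|probe_id, SYMBOL|weight or SYMBOL|probe_id|weight
# (a second field that parses as a number is a weight, otherwise a probe ID).


def _parse_member(token: str) -> SignatureMember:
    parts = token.split("|")
    symbol, probe, weight = parts[0], None, 1.0
    if len(parts) == 2:
        try:
            weight = float(parts[1])
        except ValueError:
            probe = parts[1]
    elif len(parts) == 3:
        probe = parts[1]
        weight = float(parts[2])
    elif len(parts) > 3:
        raise ValueError(f"malformed GMT member {token!r}")
    return SignatureMember(symbol=symbol, probe_id=probe, weight=weight)


def read_gmt(path) -> list[GeneSignature]:
    """Parse a GMT file (name, description, tab-separated members)."""
    signatures = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"GMT line with fewer than 3 fields: {line[:60]!r}")
            name, _desc, tokens = fields[0], fields[1], fields[2:]
            members = [_parse_member(t) for t in tokens if t]
            aggregation = "mean"
            if len(members) == 1:
                aggregation = "single_gene"
            elif any(m.weight != 1.0 for m in members):
                aggregation = "weighted_mean"
            signatures.append(GeneSignature(name=name, members=members, aggregation=aggregation))
    return signatures


def write_gmt(signatures: list[GeneSignature], path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            tokens = []
            for m in sig.members:
                token = m.symbol
                if m.probe_id is not None:
                    token += f"|{m.probe_id}"
                if m.weight != 1.0:
                    token += f"|{m.weight:g}"
                tokens.append(token)
            fh.write("\t".join([sig.name, sig.aggregation] + tokens) + "\n")


def _bundled(name: str):
    return resources.files("mksers.data").joinpath(name)


def load_mks_ers() -> dict[str, GeneSignature]:
    """The shipped MKS (12 mitotic kinases) and ERS (4 estrogen-module genes)."""
    with resources.as_file(_bundled("mks_ers.gmt")) as path:
        sigs = {s.name: s for s in read_gmt(path)}
    assert len(sigs["MKS"].members) == 12 and len(sigs["ERS"].members) == 4
    return sigs


def load_default_panel() -> list[GeneSignature]:
    """Bundled biomarker panel (synthetic placeholder member lists).

    RBsig, IRPS, TILs metagene and T-cell-inflamed GEP member lists here are
    synthetic stand-ins for the published signatures (see docs/methods.md);
    CCNE1 is the real single-gene marker.
    """
    with resources.as_file(_bundled("biomarker_panel_synthetic.gmt")) as path:
        return read_gmt(path)


# ---------------------------------------------------------------------------
# Resolution and filtering


def resolve_features(signature: GeneSignature, matrix: ExpressionMatrix) -> list[str]:
    """Map a signature to matrix feature IDs.

    On Affymetrix-tagged platforms a signature carrying probe IDs matches by
    probe-set ID; otherwise matching is by gene symbol, case-insensitive.
    Order is deterministic: signature member order, then matrix feature order
    within a member. Raises :class:`SignatureUnrepresentedError` when nothing
    matches.
    """
    if matrix.n_features == 0 or matrix.n_samples == 0:
        raise ValueError("matrix is empty")
    features = matrix.feature_ids
    resolved: list[str] = []
    seen: set[str] = set()
    if matrix.is_affymetrix and signature.has_probes:
        index = set(features)
        for m in signature.members:
            if m.probe_id in index and m.probe_id not in seen:
                resolved.append(m.probe_id)
                seen.add(m.probe_id)
    else:
        by_symbol: dict[str, list[str]] = {}
        for f in features:
            by_symbol.setdefault(f.upper(), []).append(f)
        for m in signature.members:
            for f in by_symbol.get(m.symbol.upper(), []):
                if f not in seen:
                    resolved.append(f)
                    seen.add(f)
    if not resolved:
        raise SignatureUnrepresentedError(
            f"signature {signature.name!r} unrepresented on this matrix"
        )
    return resolved


def filter_discordant_probes(
    matrix: ExpressionMatrix,
    candidate_features: list[str],
    r_min: float = DEFAULT_PROBE_R_MIN,
) -> list[str]:
    """Drop features discordant with the main co-expression cluster.

    Pairwise Pearson correlation r is computed among candidates across samples;
    average-linkage hierarchical clustering on distance 1 - r is cut at height
    1 - r_min and the largest cluster is retained (ties broken toward the
    cluster containing the lexicographically smallest feature ID). Features
    with zero variance are excluded beforehand with a warning. Idempotent:
    re-running on its own output changes nothing.
    """
    if len(candidate_features) < 2:
        raise ValueError("need at least 2 candidate features")
    sub = matrix.values.loc[candidate_features]
    n_obs = sub.notna().sum(axis=1)
    if (n_obs < 3).any():
        bad = list(sub.index[n_obs < 3])
        raise ValueError(f"features with <3 non-missing samples: {bad}")
    sd = sub.std(axis=1, ddof=1)
    degenerate = list(sub.index[(sd == 0) | sd.isna()])
    if degenerate:
        warnings.warn(
            f"excluding zero-variance features before clustering: {degenerate}",
            RuntimeWarning,
            stacklevel=2,
        )
        sub = sub.drop(index=degenerate)
    kept = [str(f) for f in sub.index]
    if len(kept) <= 1:
        if not kept:
            raise ValueError("all candidate features have degenerate variance")
        return kept
    corr = sub.T.corr(method="pearson")
    # pairs with no usable overlap carry no evidence of concordance: treat as r=0
    corr = corr.fillna(0.0)
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(z, t=1.0 - r_min, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for feat, lab in zip(kept, labels):
        clusters.setdefault(int(lab), []).append(feat)
    max_size = max(len(c) for c in clusters.values())
    tied = [c for c in clusters.values() if len(c) == max_size]
    best = min(tied, key=lambda c: min(c))
    best_set = set(best)
    return [f for f in kept if f in best_set]


def score_metagene(
    matrix: ExpressionMatrix, signature: GeneSignature, features: list[str]
) -> np.ndarray:
    """Per-sample (weighted) mean log-expression over the given features.

    Missing entries are handled by the within-sample available-feature mean;
    a sample with every feature missing raises. ``single_gene`` signatures
    return that feature's row unchanged.
    """
    if not features:
        raise SignatureUnrepresentedError(f"no features supplied for {signature.name!r}")
    sub = matrix.values.loc[features]
    if signature.aggregation == "single_gene":
        row = sub.iloc[0].to_numpy(dtype=float)
        if np.isnan(row).any():
            raise ValueError(f"missing values in single-gene signature {signature.name!r}")
        return row
    weights = _feature_weights(signature, features, matrix)
    vals = sub.to_numpy(dtype=float)
    w = weights[:, None] * np.ones_like(vals)
    w[np.isnan(vals)] = 0.0
    denom = w.sum(axis=0)
    if np.any(denom == 0):
        bad = [s for s, d in zip(matrix.sample_ids, denom) if d == 0]
        raise ValueError(f"all signature features missing for samples {bad[:5]}")
    return np.nansum(w * np.nan_to_num(vals), axis=0) / denom


def _feature_weights(
    signature: GeneSignature, features: list[str], matrix: ExpressionMatrix
) -> np.ndarray:
    if signature.aggregation != "weighted_mean":
        return np.ones(len(features))
    by_probe = {m.probe_id: m.weight for m in signature.members if m.probe_id}
    by_symbol = {m.symbol.upper(): m.weight for m in signature.members}
    out = []
    for f in features:
        if f in by_probe:
            out.append(by_probe[f])
        else:
            out.append(by_symbol.get(f.upper(), 1.0))
    return np.asarray(out, dtype=float)


def score_panel(
    matrix: ExpressionMatrix,
    panel: list[GeneSignature],
    probe_filter: str | bool = "auto",
    r_min: float = DEFAULT_PROBE_R_MIN,
) -> ScoreTable:
    """Score every signature of a panel; unrepresented ones are recorded, not fatal.

    ``probe_filter="auto"`` runs the discordant-probe filter only when some
    gene resolves to more than one feature (multi-probe platform); ``True``
    forces it whenever >=2 features resolve, ``False`` disables it.
    """
    table = ScoreTable(sample_ids=matrix.sample_ids)
    for sig in panel:
        try:
            feats = resolve_features(sig, matrix)
        except SignatureUnrepresentedError:
            warnings.warn(f"signature {sig.name!r} unrepresented; skipped", RuntimeWarning,
                          stacklevel=2)
            table.unrepresented.append(sig.name)
            continue
        multi_probe = len(feats) > len(set(_symbols_of(sig, feats)))
        do_filter = probe_filter is True or (probe_filter == "auto" and multi_probe)
        if do_filter and len(feats) >= 2:
            feats = filter_discordant_probes(matrix, feats, r_min=r_min)
        table.add(sig.name, score_metagene(matrix, sig, feats), len(feats))
    return table


def _symbols_of(signature: GeneSignature, features: list[str]) -> list[str]:
    """Gene symbol owning each resolved feature (for multi-probe detection)."""
    by_probe = {m.probe_id: m.symbol for m in signature.members if m.probe_id}
    symbols = {m.symbol.upper() for m in signature.members}
    out = []
    for f in features:
        if f in by_probe:
            out.append(by_probe[f].upper())
        elif f.upper() in symbols:
            out.append(f.upper())
        else:
            out.append(f.upper())
    return out
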