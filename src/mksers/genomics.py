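"""Mutation-table analysis: TMB, top mutated genes, subgroup frequency tests.

Works on MAF-subset tables with at least Tumor_Sample_Barcode, Hugo_Symbol and
Variant_Classification columns (short aliases sample_id / gene /
variant_classification are accepted). Tumour mutational burden is the raw
count of coding mutations per sample — synonymous and non-synonymous alike —
not a per-megabase rate.
"""

from __future__ import annotations

import warnings
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "CODING_CLASSES",
    "NONCODING_CLASSES",
    "read_maf",
    "load_default_exclusion",
    "compute_tmb",
    "top_mutated_genes",
    "frequency_table_and_test",
    "cmh_general_association",
]

# Variant classes counted in TMB ("synonymous and non-synonymous" coding events)
CODING_CLASSES = frozenset({
    "Missense_Mutation", "Nonsense_Mutation", "Nonstop_Mutation", "Silent",
    "Splice_Site", "Frame_Shift_Ins", "Frame_Shift_Del",
    "In_Frame_Ins", "In_Frame_Del", "Translation_Start_Site",
})
NONCODING_CLASSES = frozenset({
    "Intron", "3'UTR", "5'UTR", "3'Flank", "5'Flank", "IGR", "RNA",
    "Targeted_Region", "Splice_Region",
})

_ALIASES = {
    "Tumor_Sample_Barcode": "sample_id",
    "Hugo_Symbol": "gene",
    "Variant_Classification": "variant_classification",
}


def _normalise(muts: pd.DataFrame) -> pd.DataFrame:
    df = muts.rename(columns=_ALIASES)
    required = {"sample_id", "gene", "variant_classification"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mutation table missing columns: {sorted(missing)}")
    if (df["gene"].astype(str).str.len() == 0).any():
        raise ValueError("empty gene symbols in mutation table")
    return df


def read_maf(path) -> pd.DataFrame:
    """Read a MAF-subset TSV (standard MAF column names or short aliases)."""
    return _normalise(pd.read_csv(path, sep="\t", comment="#"))


def load_default_exclusion() -> list[str]:
    """Bundled default non-driver exclusion list (recurrent passengers)."""
    text = resources.files("mksers.data").joinpath("nondriver_exclusion.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def _is_coding(classifications: pd.Series, strict: bool) -> pd.Series:
    known = CODING_CLASSES | NONCODING_CLASSES
    unknown = set(classifications.unique()) - known
    if unknown:
        msg = f"unknown variant classifications: {sorted(unknown)}"
        if strict:
            raise ValueError(msg)
        warnings.warn(msg + " (excluded from coding counts)", RuntimeWarning, stacklevel=3)
    return classifications.isin(CODING_CLASSES)


def compute_tmb(muts: pd.DataFrame, samples: list[str], strict: bool = False) -> pd.Series:
    """Coding mutations per sample; samples absent from the table count 0."""
    df = _normalise(muts)
    coding = df[_is_coding(df["variant_classification"], strict)]
    counts = coding.groupby("sample_id").size()
    return counts.reindex([str(s) for s in samples], fill_value=0).rename("tmb").astype(int)


def top_mutated_genes(
    muts: pd.DataFrame,
    samples: list[str],
    k: int = 15,
    exclusion: list[str] | None = None,
    strict: bool = False,
) -> list[str]:
    """Top-k genes by fraction of samples carrying >=1 coding mutation.

    Exclusion-list genes (non-drivers) are removed before ranking; ties are
    broken alphabetically. Returns min(k, available) genes.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    df = _normalise(muts)
    samples = [str(s) for s in samples]
    df = df[df["sample_id"].isin(samples)]
    coding = df[_is_coding(df["variant_classification"], strict)]
    excl = {g.upper() for g in (exclusion or [])}
    frac = (
        coding[~coding["gene"].str.upper().isin(excl)]
        .groupby("gene")["sample_id"].nunique() / max(len(samples), 1)
    )
    ranked = frac.sort_index().sort_values(ascending=False, kind="stable")
    return list(ranked.index[:k])


def mutated_indicator(muts: pd.DataFrame, gene: str, samples: list[str]) -> np.ndarray:
    """Boolean vector: sample has >=1 coding mutation in `gene`."""
    df = _normalise(muts)
    coding = df[_is_coding(df["variant_classification"], strict=False)]
    hit = set(coding.loc[coding["gene"].str.upper() == gene.upper(), "sample_id"])
    return np.array([str(s) in hit for s in samples], dtype=bool)


def cmh_general_association(tables: list[np.ndarray]) -> tuple[float, int, float]:
    """Cochran–Mantel–Haenszel general-association statistic for 2 x G strata.

    Each stratum is a 2 x G count table (rows: trait present/absent, columns:
    groups). With a single stratum and G=2 this reduces to the classical
    Mantel–Haenszel chi-square, i.e. (N-1)/N times the Pearson chi-square.
    Returns (statistic, df, p); df = G - 1.
    """
    tables = [np.asarray(t, dtype=float) for t in tables]
    G = tables[0].shape[1]
    if any(t.shape != (2, G) for t in tables):
        raise ValueError("all strata must be 2 x G tables with equal G")
    d = G - 1
    diff = np.zeros(d)
    V = np.zeros((d, d))
    for t in tables:
        N = t.sum()
        if N <= 1:
            continue
        row1 = t[0].sum()
        row2 = t[1].sum()
        n_g = t.sum(axis=0)
        O = t[0, :d]
        E = n_g[:d] * row1 / N
        cov = (row1 * row2 / (N**2 * (N - 1))) * (N * np.diag(n_g[:d]) - np.outer(n_g[:d], n_g[:d]))
        diff += O - E
        V += cov
    if not np.any(V):
        return 0.0, d, 1.0
    stat = float(diff @ np.linalg.solve(V, diff)) if np.linalg.matrix_rank(V) == d else float(
        diff @ np.linalg.pinv(V) @ diff
    )
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, d)) if stat > 0 else 1.0
    return stat, d, p


def frequency_table_and_test(
    muts: pd.DataFrame,
    labels: pd.Series,
    genes: list[str],
    stratum: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene mutation frequency by subgroup plus a CMH association test.

    ``labels`` maps sample_id -> subgroup (NA labels are dropped). For each
    gene a 2 x G table (mutated vs not, across subgroups) is tested with the
    CMH general-association statistic (single stratum unless ``stratum``
    supplies one). Genes absent from the table get frequency 0 everywhere and
    the test is skipped with a note.
    """
    labels = labels.dropna().astype(str)
    groups = sorted(labels.unique())
    if len(groups) < 2:
        raise ValueError("need >=2 subgroups with >=1 sample")
    samples = list(labels.index.astype(str))
    strat = (stratum.reindex(labels.index).astype(str)
             if stratum is not None else pd.Series("all", index=labels.index))
    rows = []
    for gene in genes:
        ind = pd.Series(mutated_indicator(muts, gene, samples), index=labels.index)
        freqs = {g: float(ind[labels == g].mean()) for g in groups}
        if not ind.any():
            rows.append({"gene": gene, **freqs, "statistic": np.nan, "df": len(groups) - 1,
                         "p_value": np.nan, "note": "gene absent; test skipped"})
            continue
        tables = []
        for s in strat.unique():
            mask = strat == s
            t = np.zeros((2, len(groups)))
            for j, g in enumerate(groups):
                in_cell = mask & (labels == g)
                t[0, j] = int((ind & in_cell).sum())
                t[1, j] = int((~ind & in_cell).sum())
            tables.append(t)
        stat, df_, p = cmh_general_association(tables)
        rows.append({"gene": gene, **freqs, "statistic": stat, "df": df_, "p_value": p,
                     "note": ""})
    return pd.DataFrame(rows).set_index("gene")
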