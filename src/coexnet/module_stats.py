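"""Module-trait correlation, eigengene summaries, membership, hub genes.

Module-trait association correlates each module eigengene with each
trait vector. Categorical traits are one-hot encoded (one 0/1 indicator
per level) because correlating against arbitrary integer codes is
meaningless; the encoding map is kept alongside the results. P-values
come from the usual t statistic t = r*sqrt((n-2)/(1-r^2)) on n-2
degrees of freedom, two-sided, with Benjamini-Hochberg adjustment
across the whole module x trait grid.

Module membership kME is the correlation of a feature's profile with a
module eigengene; hub genes are ranked by kME to their own module with
intramodular connectivity as tie-breaker and feature id as final tie.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from coexnet.core_data import ExpressionDataset
from coexnet.module_detection import EigengeneSet, ModuleAssignment
from coexnet.network import CoexpressionNetwork

logger = logging.getLogger(__name__)


@dataclass
class TraitCorrelationTable:
    """Long-format (module, trait) correlation results."""

    table: pd.DataFrame  # module_label, trait, r, p_value, p_adjusted
    trait_encoding: dict[str, list[str]]  # categorical column -> indicator names

    def pivot(self, value: str = "r") -> pd.DataFrame:
        return self.table.pivot(index="module_label", columns="trait", values=value)


@dataclass
class MembershipTable:
    """kME for every (feature, module) and intramodular connectivity."""

    kme: pd.DataFrame  # features x module labels
    intramodular_connectivity: pd.Series  # feature -> sum of adjacency to own module


def encode_traits(sample_meta: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, list[str]]]:
    """Numeric columns pass through; categoricals become 0/1 indicators."""
    cols: dict[str, np.ndarray] = {}
    encoding: dict[str, list[str]] = {}
    for col in sample_meta.columns:
        s = sample_meta[col]
        if pd.api.types.is_numeric_dtype(s) and not isinstance(s.dtype, pd.CategoricalDtype):
            cols[col] = s.to_numpy(dtype=float)
        else:
            levels = [l for l in pd.unique(s.dropna())]
            names = []
            for level in levels:
                name = f"{col}={level}"
                cols[name] = (s == level).to_numpy(dtype=float)
                names.append(name)
            encoding[col] = names
    return pd.DataFrame(cols, index=sample_meta.index), encoding


def _corr_pvalue(r: float, n: int) -> float:
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def module_trait_correlation(
    eig: EigengeneSet,
    sample_meta: pd.DataFrame,
    method: str = "pearson",
) -> TraitCorrelationTable:
    """Correlate every module eigengene with every (encoded) trait.

    A constant trait column yields undefined (NaN) cells with a warning
    rather than an error. Adjusted p-values are BH across all finite
    cells of the grid.
    """
    if method != "pearson":
        raise ValueError("only pearson module-trait correlation is supported")
    meta = sample_meta.reindex(eig.sample_ids)
    traits, encoding = encode_traits(meta)
    n = len(eig.sample_ids)
    if n < 3:
        raise ValueError("need at least 3 samples for module-trait correlation")
    rows = []
    for label in eig.module_labels:
        e = eig.eigengene(label)
        for trait in traits.columns:
            tv = traits[trait].to_numpy()
            ok = np.isfinite(tv)
            if ok.sum() < 3 or np.std(tv[ok]) == 0:
                logger.warning("trait %r is constant or too sparse; cells undefined", trait)
                rows.append({"module_label": label, "trait": trait, "r": np.nan, "p_value": np.nan})
                continue
            r = float(np.corrcoef(e[ok], tv[ok])[0, 1])
            rows.append(
                {"module_label": label, "trait": trait, "r": r, "p_value": _corr_pvalue(r, int(ok.sum()))}
            )
    table = pd.DataFrame(rows)
    table["p_adjusted"] = np.nan
    finite = table["p_value"].notna()
    if finite.any():
        table.loc[finite, "p_adjusted"] = multipletests(
            table.loc[finite, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    return TraitCorrelationTable(table=table, trait_encoding=encoding)


def summarize_eigengene_by_category(
    eig: EigengeneSet,
    sample_meta: pd.DataFrame,
    category: str,
) -> pd.DataFrame:
    """Per-(module, level) eigengene mean/SD/count plus per-sample values.

    Returns a long table with one row per (module, sample) carrying the
    sample's eigengene value, its level, and the level's mean, standard
    deviation and count — ready for a bars-plus-points summary plot.
    """
    if category not in sample_meta.columns:
        raise ValueError(f"unknown sample metadata category {category!r}")
    meta = sample_meta.reindex(eig.sample_ids)
    levels = meta[category]
    records = []
    for label in eig.module_labels:
        e = pd.Series(eig.eigengene(label), index=eig.sample_ids)
        for level, group in e.groupby(levels):
            for sid, val in group.items():
                records.append(
                    {
                        "module_label": label,
                        "level": level,
                        "sample_id": sid,
                        "eigengene": float(val),
                        "level_mean": float(group.mean()),
                        "level_sd": float(group.std(ddof=1)) if len(group) > 1 else 0.0,
                        "level_n": int(len(group)),
                    }
                )
    return pd.DataFrame(records)


def module_membership(
    ds: ExpressionDataset,
    eig: EigengeneSet,
    net: CoexpressionNetwork,
    assignment: ModuleAssignment,
) -> MembershipTable:
    """kME of every feature against every module eigengene, plus
    intramodular connectivity from the adjacency restricted to the
    feature's own module."""
    if net.feature_ids != ds.feature_ids:
        raise ValueError("network and dataset feature ids are not aligned")
    X = ds.values
    Xc = X - X.mean(axis=0)
    Xn = Xc / np.linalg.norm(Xc, axis=0)
    kme = {}
    for label in eig.module_labels:
        e = eig.eigengene(label)
        ec = e - e.mean()
        en = ec / np.linalg.norm(ec)
        kme[label] = np.clip(Xn.T @ en, -1.0, 1.0)
    kme_df = pd.DataFrame(kme, index=ds.feature_ids)
    labels = assignment.labels.reindex(ds.feature_ids)
    adj = net.adjacency
    conn = np.zeros(ds.n_features)
    lab_arr = labels.to_numpy()
    for label in assignment.module_labels:
        idx = np.flatnonzero(lab_arr == label)
        sub = adj[np.ix_(idx, idx)]
        conn[idx] = sub.sum(axis=1) - np.diag(sub)
    return MembershipTable(
        kme=kme_df,
        intramodular_connectivity=pd.Series(conn, index=ds.feature_ids, name="intramodular_connectivity"),
    )


def hub_genes(
    membership: MembershipTable,
    assignment: ModuleAssignment,
    top_n: int = 10,
) -> dict[int, pd.DataFrame]:
    """Top hub features per module, ranked by kME to the own module,
    then intramodular connectivity, then feature id (ascending)."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    out: dict[int, pd.DataFrame] = {}
    for label in assignment.module_labels:
        feats = assignment.features_in(label)
        df = pd.DataFrame(
            {
                "kME": membership.kme.loc[feats, label],
                "intramodular_connectivity": membership.intramodular_connectivity.loc[feats],
            }
        )
        df = df.sort_values(
            by=["kME", "intramodular_connectivity", "feature_id"]
            if "feature_id" in df.columns
            else ["kME", "intramodular_connectivity"],
            ascending=[False, False],
            kind="stable",
        )
        # final tie-break: lexicographic feature id
        df = (
            df.reset_index(names="feature_id")
            .sort_values(
                by=["kME", "intramodular_connectivity", "feature_id"],
                ascending=[False, False, True],
                kind="stable",
            )
            .set_index("feature_id")
        )
        out[label] = df.head(top_n)
    return out
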