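"""Phylogenetic comparative statistics.

Gene-count and brain-cell data are modelled with generalized least squares
under a Brownian-motion residual covariance derived from a time-calibrated
tree: Cov(i, j) equals the depth of the most recent common ancestor of
tips i and j. Fits report coefficient estimates, standard errors, t
statistics and two-sided p-values with n - p degrees of freedom; the
residual rate sigma^2 is estimated by REML by default (ML optional).

Also here: FAN (freshwater + amphibious + nocturnal) trait classification,
group contrasts on log10 gene counts, and the olfactory-bulb cell model
(log10 OB cells ~ log10 rest-of-brain cells + log10 receptor count).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import linalg, stats

SALINITY_LEVELS = ("marine", "freshwater", "brackish")
ACTIVITY_LEVELS = ("nocturnal", "diurnal", "arrhythmic", "unknown")


@dataclass
class PglsFit:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float
    df_resid: int
    loglik: float
    residuals: pd.Series
    method: str

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        half = stats.t.ppf(1 - alpha / 2, self.df_resid) * self.bse
        return pd.DataFrame(
            {"lower": self.params - half, "upper": self.params + half}
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )


def brownian_cov(tree: dendropy.Tree | str) -> pd.DataFrame:
    """Brownian covariance matrix from a tree with branch lengths.

    Entry (i, j) is the root-to-MRCA path length of tips i and j; the
    diagonal holds root-to-tip depths. Species order is sorted taxon label.
    """
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is None:
            raise ValueError("tree has edges without branch lengths")
    labels = sorted(t.label for t in tree.taxon_namespace)
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate tip labels")
    index = {label: i for i, label in enumerate(labels)}
    n = len(labels)
    cov = np.zeros((n, n))
    depth: dict[dendropy.Node, float] = {}
    for node in tree.preorder_node_iter():
        parent_depth = depth.get(node.parent_node, 0.0)
        depth[node] = parent_depth + (node.edge.length or 0.0)
        if node.is_leaf():
            i = index[node.taxon.label]
            cov[i, i] = depth[node]
        else:
            children = node.child_nodes()
            tipsets = [
                [index[leaf.taxon.label] for leaf in child.leaf_iter()]
                for child in children
            ]
            for a in range(len(tipsets)):
                for b in range(a + 1, len(tipsets)):
                    for i in tipsets[a]:
                        for j in tipsets[b]:
                            cov[i, j] = cov[j, i] = depth[node]
    return pd.DataFrame(cov, index=labels, columns=labels)


def pgls(
    y: pd.Series,
    X: pd.DataFrame,
    C: pd.DataFrame,
    method: str = "REML",
) -> PglsFit:
    """Generalized least squares under a (Brownian) covariance structure.

    beta = (X' C^-1 X)^-1 X' C^-1 y; sigma^2 is the REML (default) or ML
    estimate of the residual rate; standard errors come from
    sigma^2 (X' C^-1 X)^-1; t-based two-sided p-values use n - p degrees
    of freedom. A tiny ridge (1e-10 of the trace) is added if the Cholesky
    factorization of C fails.
    """
    order = list(y.index)
    Xm = X.loc[order].to_numpy(dtype=float)
    ym = y.to_numpy(dtype=float)
    Cm = C.loc[order, order].to_numpy(dtype=float)
    n, p = Xm.shape
    if n <= p:
        raise ValueError("more parameters than observations")
    try:
        chol = linalg.cholesky(Cm, lower=True)
    except linalg.LinAlgError:
        Cm = Cm + np.eye(n) * 1e-10 * np.trace(Cm)
        chol = linalg.cholesky(Cm, lower=True)
    # whiten: solve L z = v
    Xw = linalg.solve_triangular(chol, Xm, lower=True)
    yw = linalg.solve_triangular(chol, ym, lower=True)
    XtX = Xw.T @ Xw
    if np.linalg.cond(XtX) > 1e12:
        raise ValueError("singular design matrix")
    beta = linalg.solve(XtX, Xw.T @ yw, assume_a="pos")
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    df = n - p
    sigma2 = rss / df if method.upper() == "REML" else rss / n
    cov_beta = linalg.inv(XtX) * sigma2
    bse = np.sqrt(np.diag(cov_beta))
    tvals = beta / bse
    pvals = 2 * stats.t.sf(np.abs(tvals), df)
    logdet_c = 2 * np.log(np.diag(chol)).sum()
    if method.upper() == "REML":
        sign, logdet_xtx = np.linalg.slogdet(XtX)
        loglik = -0.5 * (
            df * np.log(2 * np.pi * sigma2) + logdet_c + logdet_xtx + df
        )
    else:
        loglik = -0.5 * (n * np.log(2 * np.pi * sigma2) + logdet_c + n)
    resid = ym - Xm @ beta
    cols = list(X.columns)
    return PglsFit(
        params=pd.Series(beta, index=cols),
        bse=pd.Series(bse, index=cols),
        tvalues=pd.Series(tvals, index=cols),
        pvalues=pd.Series(pvals, index=cols),
        sigma2=sigma2,
        df_resid=df,
        loglik=float(loglik),
        residuals=pd.Series(resid, index=order),
        method=method.upper(),
    )


def _align_tree_table(
    traits: pd.DataFrame, C: pd.DataFrame, required: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Intersect species between table and tree; drop incomplete rows."""
    usable = traits.dropna(subset=required)
    common = sorted(set(usable.index) & set(C.index))
    dropped = sorted(set(traits.index) - set(common))
    return usable.loc[common], C.loc[common, common], dropped


def ob_cell_model(
    traits: pd.DataFrame,
    tree: dendropy.Tree | str,
    method: str = "REML",
) -> tuple[PglsFit, pd.DataFrame, list[str]]:
    """The olfactory-bulb cellularity model.

    Fits log10(OB cells) ~ log10(rest-of-brain cells) + log10(OLF genes)
    under the Brownian covariance. Also returns the residual table used for
    plotting (residuals of OB ~ rest-of-brain against receptor counts) and
    the list of species dropped for missing data.
    """
    C = brownian_cov(tree)
    table, C, dropped = _align_tree_table(
        traits, C, ["ob_cells", "rest_brain_cells", "olf_total"]
    )
    y = np.log10(table["ob_cells"].astype(float))
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "log10_rest_brain": np.log10(table["rest_brain_cells"].astype(float)),
            "log10_olf": np.log10(table["olf_total"].astype(float)),
        },
        index=table.index,
    )
    fit = pgls(y, X, C, method=method)
    base = pgls(y, X[["intercept", "log10_rest_brain"]], C, method=method)
    residual_table = pd.DataFrame(
        {
            "olf_total": table["olf_total"],
            "ob_residual": base.residuals,
        }
    )
    return fit, residual_table, dropped


def fan_classify(traits: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Species that are freshwater, amphibious and nocturnal.

    Returns (FAN species, species excluded for unknown activity).
    """
    excluded = sorted(traits.index[traits["activity"] == "unknown"])
    known = traits[traits["activity"] != "unknown"]
    fan = known[
        (known["salinity"] == "freshwater")
        & known["amphibious"].astype(bool)
        & (known["activity"] == "nocturnal")
    ]
    return sorted(fan.index), excluded


def group_contrast(
    counts: pd.Series,
    indicator: pd.Series,
    tree: dendropy.Tree | str,
    method: str = "REML",
) -> PglsFit:
    """PGLS of log10 gene counts on a binary group indicator."""
    values = sorted(set(indicator.dropna()))
    if len(values) < 2:
        raise ValueError("indicator is degenerate (single group)")
    C = brownian_cov(tree)
    common = sorted(set(counts.index) & set(indicator.index) & set(C.index))
    y = np.log10(counts.loc[common].astype(float))
    X = pd.DataFrame(
        {"intercept": 1.0, "group": indicator.loc[common].astype(float)},
        index=common,
    )
    return pgls(y, X, C.loc[common, common], method=method)


def group_summaries(
    counts: pd.Series, traits: pd.DataFrame
) -> pd.DataFrame:
    """Median/quartile summaries for the non-exclusive ecological groups."""
    fan, _ = fan_classify(traits)
    amphibious = traits.index[traits["amphibious"].astype(bool)]
    groups = {
        "freshwater": traits.index[traits["salinity"] == "freshwater"],
        "amphibious": amphibious,
        "nocturnal": traits.index[traits["activity"] == "nocturnal"],
        "FAN": pd.Index(fan),
        "amphibious_nocturnal": [
            s for s in amphibious if traits.at[s, "activity"] == "nocturnal"
        ],
        "amphibious_diurnal": [
            s for s in amphibious if traits.at[s, "activity"] == "diurnal"
        ],
    }
    rows = []
    for name, members in groups.items():
        values = counts.loc[[m for m in members if m in counts.index]]
        rows.append(
            {
                "group": name,
                "n": len(values),
                "median": float(values.median()) if len(values) else np.nan,
                "q1": float(values.quantile(0.25)) if len(values) else np.nan,
                "q3": float(values.quantile(0.75)) if len(values) else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("group")
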