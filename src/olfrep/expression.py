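"""Olfactory-organ expression statistics.

Counts come in as per-replicate unique counts plus shared ambiguity
classes (reads compatible with several near-identical receptors). An EM
step splits each ambiguity class by current abundance; relative abundances
are computed within replicates and averaged; downstream statistics follow:
family genomic-versus-transcriptomic proportions, the
expression-concentration statistic (fraction of receptors accumulating
half of total expression), per-cluster accumulated (AcEx) and average
(AvEx) expression, and reads-per-million tissue comparisons.

No transcript-length normalization is applied: receptors within a family
are nearly equal in length, so read counts are proportional to molarity
up to a common factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .clusters import GeneCluster


def em_assign(
    unique_counts: pd.Series,
    ambig: pd.DataFrame | None = None,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> tuple[pd.Series, bool]:
    """Expectation-maximization rescue of ambiguous reads.

    ``unique_counts`` holds per-transcript uniquely assigned reads;
    ``ambig`` rows carry ``members`` (';'-separated transcript ids) and
    ``count``. The E-step splits each class proportionally to the current
    abundance of its members; the M-step re-estimates abundances; iteration
    stops when the abundance vector moves less than ``tol`` in sup-norm.

    Returns (expected counts summing to the total input reads, converged).
    """
    if (unique_counts < 0).any():
        raise ValueError("counts must be non-negative")
    ids = list(unique_counts.index)
    index = {g: i for i, g in enumerate(ids)}
    u = unique_counts.to_numpy(dtype=float)
    classes: list[tuple[np.ndarray, float]] = []
    if ambig is not None and len(ambig):
        for _, row in ambig.iterrows():
            members = [m for m in str(row["members"]).split(";") if m]
            if len(members) < 2:
                raise ValueError("ambiguity classes must list >= 2 transcripts")
            classes.append(
                (np.array([index[m] for m in members]), float(row["count"]))
            )
    total = u.sum() + sum(c for _, c in classes)
    if total == 0:
        return pd.Series(u, index=ids), True
    theta = np.full(len(ids), 1.0 / len(ids))
    converged = False
    expected = u.copy()
    for _ in range(max_iter):
        expected = u.copy()
        for members, count in classes:
            weights = theta[members]
            s = weights.sum()
            share = weights / s if s > 0 else np.full(len(members), 1 / len(members))
            expected[members] += count * share
        new_theta = expected / total
        if np.abs(new_theta - theta).max() < tol:
            theta = new_theta
            converged = True
            break
        theta = new_theta
    return pd.Series(expected, index=ids), converged


def em_assign_table(
    counts: pd.DataFrame, ambig: pd.DataFrame | None = None, **kwargs
) -> pd.DataFrame:
    """Apply :func:`em_assign` column-wise over replicates."""
    out = {}
    for col in counts.columns:
        sub = None
        if ambig is not None and len(ambig):
            sub = ambig[["members"]].copy()
            sub["count"] = ambig[col].to_numpy()
        out[col], _ = em_assign(counts[col], sub, **kwargs)
    return pd.DataFrame(out)


def drop_coreceptor(counts: pd.DataFrame, coreceptor_ids) -> pd.DataFrame:
    """Remove flagged co-expressed (co-receptor) genes before normalization.

    One highly expressed V2R singleton outside the main cluster is
    co-expressed with the rest of the family and would inflate the V2R
    share; it is excluded upstream of the abundance computation.
    """
    drop = [g for g in coreceptor_ids if g in counts.index]
    return counts.drop(index=drop)


def relative_abundance(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-replicate relative abundances plus their replicate mean.

    Each replicate column is normalized to fractions; the per-gene mean of
    the replicate fractions is renormalized to sum exactly to one and
    returned in a ``mean`` column.
    """
    if counts.shape[1] < 1:
        raise ValueError("at least one replicate required")
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"replicate(s) with zero total counts: {bad}")
    fractions = counts / totals
    mean = fractions.mean(axis=1)
    fractions = fractions.copy()
    fractions["mean"] = mean / mean.sum()
    return fractions


def family_proportions(
    abundance: pd.Series, families: pd.Series
) -> pd.DataFrame:
    """Genomic vs transcriptomic share of each receptor family.

    Genomic fraction is the family's share of gene count; transcriptomic
    fraction is its summed relative abundance. Both columns sum to one.
    """
    fam = families.loc[abundance.index]
    genomic = fam.value_counts(normalize=True).sort_index()
    transcriptomic = abundance.groupby(fam).sum().sort_index()
    out = pd.DataFrame(
        {"genomic_fraction": genomic, "transcriptomic_fraction": transcriptomic}
    ).fillna(0.0)
    out.index.name = "family"
    return out


def expression_concentration(abundance: pd.Series) -> float:
    """Fraction of receptors accumulating half of total expression.

    Abundances are sorted descending; the statistic is k*/N where k* is the
    smallest k whose cumulative share reaches 0.5 (boundary inclusive).
    """
    values = abundance.to_numpy(dtype=float)
    total = values.sum()
    if len(values) == 0 or total <= 0:
        raise ValueError("need at least one gene with positive abundance")
    ordered = np.sort(values)[::-1] / total
    k_star = int(np.argmax(np.cumsum(ordered) >= 0.5)) + 1
    return k_star / len(values)


def cluster_expression(
    abundance: pd.Series, clusters: list[GeneCluster]
) -> pd.DataFrame:
    """Accumulated (AcEx) and per-gene average (AvEx) cluster expression.

    AcEx is the percent of global receptor expression summed over a
    cluster's members; AvEx divides it by the member count. Every expressed
    gene must belong to exactly one cluster (singletons included), so AcEx
    sums to 100 over all clusters.
    """
    gene_to_cluster: dict[str, str] = {}
    for c in clusters:
        for g in c.members:
            if g in gene_to_cluster:
                raise ValueError(f"gene {g} assigned to more than one cluster")
            gene_to_cluster[g] = c.id
    missing = [g for g in abundance.index if g not in gene_to_cluster]
    if missing:
        raise ValueError(f"genes not mapped to any cluster: {missing[:5]}")
    rows = []
    for c in clusters:
        members = [g for g in c.members if g in abundance.index]
        acex = 100.0 * float(abundance.loc[members].sum()) if members else 0.0
        size = len(members) if members else c.size
        rows.append(
            {"cluster": c.id, "n_genes": size, "AcEx": acex,
             "AvEx": acex / size if size else 0.0}
        )
    return pd.DataFrame(rows).set_index("cluster")


def reads_per_million(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts-per-million within each library (column)."""
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError("library with zero total reads")
    return counts * 1e6 / totals


def tissue_olf_rpm(
    counts: pd.DataFrame, olf_genes, tissue_of: dict[str, str]
) -> pd.DataFrame:
    """Summed receptor RPM per tissue with the SD across its replicates."""
    rpm = reads_per_million(counts)
    olf = [g for g in olf_genes if g in rpm.index]
    sums = rpm.loc[olf].sum(axis=0)
    tissues = pd.Series({col: tissue_of[col] for col in counts.columns})
    grouped = sums.groupby(tissues)
    return pd.DataFrame(
        {"olf_rpm_mean": grouped.mean(), "olf_rpm_sd": grouped.std(ddof=1).fillna(0.0),
         "n_replicates": grouped.count()}
    )
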