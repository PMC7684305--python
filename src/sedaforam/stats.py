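"""Community statistics: normalization, ordination, permutation tests and
fossil-vs-metabarcode congruence.

Counts live in samples x taxa (or samples x OTU) DataFrames. The module
provides cumulative sum scaling (CSS) normalization, Bray-Curtis distances,
classical principal coordinates analysis (PCoA), a betadisper-style
multivariate dispersion test, PERMANOVA, Mantel correlation, the
planktonic-fraction depth profile, and WARM-group aggregation of census
counts.

Permutation p-values use the +1 correction, p = (#{T_perm >= T_obs}+1)/(n_perm+1),
and every permutation test takes an explicit seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("sedaforam.stats")

__all__ = [
    "OrdinationResult",
    "aggregate_warm",
    "css_normalize",
    "bray_curtis",
    "pcoa",
    "dispersion_test",
    "permanova",
    "mantel",
    "planktonic_fraction_profile",
    "congruence_report",
    "WARM_MORPHOSPECIES",
]

#: rare temperate/subtropical morphospecies advected by the North Atlantic
#: Current, reported as one aggregated census category
WARM_MORPHOSPECIES = [
    "Globigerinoides ruber albus",
    "Globorotalia hirsuta",
    "Globorotalia menardii",
    "Globigerina falconensis",
    "Pulleniatina obliquiloculata",
    "Trilobatus sacculifer",
    "Globigerinoides conglobatus",
    "Globigerinoides elongatus",
    "Globigerinella calida",
    "Globorotalia truncatulinoides",
    "Neogloboquadrina dutertrei",
    "Dentigloborotalia anfracta",
    "Globigerinoides ruber ruber",
    "Globigerinella siphonifera",
]


def aggregate_warm(
    census: pd.DataFrame, warm_list: list[str] | None = None
) -> pd.DataFrame:
    """Sum the listed morphospecies columns into one ``WARM`` column.

    Taxa absent from the table contribute zero; totals are conserved.
    """
    warm = WARM_MORPHOSPECIES if warm_list is None else warm_list
    present = [c for c in census.columns if c in warm]
    if not present:
        return census.copy()
    out = census.drop(columns=present).copy()
    out["WARM"] = census[present].sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def css_normalize(
    counts: pd.DataFrame,
    percentile: float | None = 0.5,
    scale: float = 1000.0,
    instability_bound: float = 0.1,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cumulative sum scaling of a samples x taxa count table.

    For each sample the scaling factor is the sum of its counts that are
    <= the ``percentile`` quantile of its *nonzero* counts; normalized values
    are ``count / factor * scale``. With ``percentile=None`` an adaptive
    percentile is chosen: the smallest value (on a 0.05 grid from 0.25) at
    which the across-sample instability of the factors — the median relative
    change of median-ratio factors between consecutive grid points — falls
    below ``instability_bound``.

    Samples with all-zero counts are excluded with a warning. Returns the
    normalized table and the per-sample factors.
    """
    counts = counts.astype(float)
    zero = counts.sum(axis=1) == 0
    if zero.any():
        logger.warning("excluding all-zero samples: %s", list(counts.index[zero]))
        counts = counts.loc[~zero]

    def factors_at(p: float) -> pd.Series:
        out = {}
        for s, row in counts.iterrows():
            nz = row[row > 0]
            q = np.quantile(nz.to_numpy(), p)
            out[s] = row[row <= q].sum()
        return pd.Series(out)

    if percentile is None:
        grid = np.arange(0.25, 1.0, 0.05)
        prev = None
        chosen = grid[-1]
        for p in grid:
            f = factors_at(p)
            rel = f / f.median()
            if prev is not None:
                change = float(np.median(np.abs(rel - prev)))
                if change < instability_bound:
                    chosen = p
                    break
            prev = rel
        percentile = float(chosen)
    factors = factors_at(percentile)
    normalized = counts.div(factors, axis=0) * scale
    return normalized, factors


# ---------------------------------------------------------------------------
# distances and ordination
# ---------------------------------------------------------------------------


def bray_curtis(table: pd.DataFrame) -> pd.DataFrame:
    """Bray-Curtis dissimilarity between sample rows.

    d(i,j) = sum|x-y| / sum(x+y); pairs of all-zero samples are undefined and
    raise.
    """
    X = table.to_numpy(dtype=float)
    if (X < 0).any():
        raise ValueError("counts must be non-negative")
    if (X.sum(axis=1) == 0).sum() >= 2:
        raise ValueError("two all-zero samples make Bray-Curtis undefined")
    D = squareform(pdist(X, metric="braycurtis"))
    return pd.DataFrame(D, index=table.index, columns=table.index)


@dataclass
class OrdinationResult:
    """Classical-scaling embedding of a distance matrix."""

    coordinates: pd.DataFrame  # samples x axes, ordered by eigenvalue
    eigenvalues: np.ndarray  # descending; may include negative values
    proportion_explained: np.ndarray
    correction: float  # additive constant applied to squared distances (0 = none)


def pcoa(
    dm: pd.DataFrame,
    correction_tol: float = 1e-8,
    correct_negative: bool = False,
) -> OrdinationResult:
    """Principal coordinates analysis by double-centered eigendecomposition.

    Negative eigenvalues (non-Euclidean input) are kept and reported; when
    ``correct_negative`` is set and the most negative eigenvalue exceeds
    ``correction_tol`` in magnitude, the additive (Lingoes) correction
    ``d^2 -> d^2 + 2c`` is applied and recorded. Axes with negative
    eigenvalues receive coordinates scaled by sqrt(|eigenvalue|); their sign
    convention matters only to consumers such as the dispersion test.
    """
    D = dm.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    n = D.shape[0]
    correction = 0.0

    def embed(D2: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        J = np.eye(n) - np.ones((n, n)) / n
        B = -0.5 * J @ D2 @ J
        vals, vecs = np.linalg.eigh(B)
        order = np.argsort(vals)[::-1]
        return vals[order], vecs[:, order]

    vals, vecs = embed(D**2)
    if correct_negative and vals.min() < -correction_tol:
        correction = -vals.min()
        D2 = D**2 + 2 * correction
        np.fill_diagonal(D2, 0.0)
        vals, vecs = embed(D2)
    coords = vecs * np.sqrt(np.abs(vals))[None, :]
    total = np.abs(vals).sum()
    prop = np.abs(vals) / total if total > 0 else np.zeros(n)
    axes = [f"PC{i + 1}" for i in range(n)]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=dm.index, columns=axes),
        eigenvalues=vals,
        proportion_explained=prop,
        correction=correction,
    )


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------


def _one_way_f(values: np.ndarray, labels: np.ndarray) -> float:
    """One-way ANOVA F statistic on a 1-D response."""
    groups = np.unique(labels)
    n, k = len(values), len(groups)
    grand = values.mean()
    ssb = sum(
        (values[labels == g].mean() - grand) ** 2 * (labels == g).sum() for g in groups
    )
    ssw = sum(((values[labels == g] - values[labels == g].mean()) ** 2).sum() for g in groups)
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    pairwise: pd.DataFrame | None = None


def _centroid_distances(
    ord_res: OrdinationResult, labels: np.ndarray, eig_tol: float = 1e-9
) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Axes with negative eigenvalues contribute negatively to the squared
    distance (the betadisper convention for non-Euclidean distances);
    negative squared distances are truncated at zero.
    """
    vals = ord_res.eigenvalues
    keep = np.abs(vals) > eig_tol
    C = ord_res.coordinates.to_numpy()[:, keep]
    sign = np.sign(vals[keep])
    d2 = np.empty(len(C))
    for g in np.unique(labels):
        idx = labels == g
        cen = C[idx].mean(axis=0)
        d2[idx] = ((C[idx] - cen) ** 2 * sign).sum(axis=1)
    return np.sqrt(np.clip(d2, 0.0, None))


def dispersion_test(
    dm: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
    pairwise: bool = False,
) -> PermutationTestResult:
    """Betadisper-style homogeneity-of-dispersion test.

    Samples are embedded by PCoA, each sample's distance to its group
    centroid is computed, and the one-way ANOVA F on these distances is
    compared with its distribution under ``n_perm`` random permutations of
    the group labels (centroids and distances are recomputed under each
    permuted labelling). Singleton groups are excluded with a warning.
    """
    labels = groups.loc[dm.index].to_numpy()
    sizes = pd.Series(labels).value_counts()
    singles = sizes[sizes < 2].index
    if len(singles):
        logger.warning("excluding singleton groups: %s", list(singles))
        keep = ~pd.Series(labels, index=dm.index).isin(singles)
        dm = dm.loc[keep, keep]
        labels = groups.loc[dm.index].to_numpy()
    if len(set(labels)) < 2:
        raise ValueError("need at least two groups with >= 2 samples")

    ord_res = pcoa(dm)

    def stat(lab: np.ndarray) -> float:
        return _one_way_f(_centroid_distances(ord_res, lab), lab)

    f_obs = stat(labels)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if stat(rng.permutation(labels)) >= f_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    pw = None
    if pairwise:
        rows = []
        gs = sorted(set(labels))
        for i, a in enumerate(gs):
            for b in gs[i + 1 :]:
                idx = np.isin(labels, [a, b])
                sub = dm.loc[idx, idx]
                res = dispersion_test(sub, groups, n_perm=n_perm, seed=seed)
                rows.append({"group_a": a, "group_b": b, "F": res.statistic, "p": res.p_value})
        pw = pd.DataFrame(rows)
    return PermutationTestResult(float(f_obs), float(p), n_perm, pw)


def permanova(
    dm: pd.DataFrame,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Permutational multivariate ANOVA (location test) on a distance matrix.

    The pseudo-F partitions the total sum of squared distances into among-
    and within-group components; significance comes from label permutations.
    """
    labels = groups.loc[dm.index].to_numpy()
    D2 = dm.to_numpy(dtype=float) ** 2
    n = len(labels)
    uniq = list(dict.fromkeys(labels))
    k = len(uniq)
    if k < 2:
        raise ValueError("need at least two groups")

    sst = D2[np.triu_indices(n, 1)].sum() / n

    def pseudo_f(lab: np.ndarray) -> float:
        ssw = 0.0
        for g in uniq:
            idx = np.nonzero(lab == g)[0]
            if len(idx) < 2:
                continue
            sub = D2[np.ix_(idx, idx)]
            ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        ssa = sst - ssw
        if ssw == 0:
            return np.inf if ssa > 0 else 0.0
        return (ssa / (k - 1)) / (ssw / (n - k))

    f_obs = pseudo_f(labels)
    rng = np.random.default_rng(seed)
    exceed = sum(pseudo_f(rng.permutation(labels)) >= f_obs for _ in range(n_perm))
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult(float(f_obs), float(p), n_perm)


def mantel(
    dm_a: pd.DataFrame,
    dm_b: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
) -> PermutationTestResult:
    """Mantel correlation between two distance matrices over shared samples.

    Pearson correlation of the condensed upper triangles; the permutation
    null shuffles the sample order of the second matrix.
    """
    shared = dm_a.index.intersection(dm_b.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    A = dm_a.loc[shared, shared].to_numpy(dtype=float)
    B = dm_b.loc[shared, shared].to_numpy(dtype=float)
    iu = np.triu_indices(len(shared), 1)

    def corr(b: np.ndarray) -> float:
        x, y = A[iu], b[iu]
        if x.std() == 0 or y.std() == 0:
            return 0.0
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(B)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(shared))
        if corr(B[np.ix_(perm, perm)]) >= r_obs:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)
    return PermutationTestResult(r_obs, float(p), n_perm)


# ---------------------------------------------------------------------------
# depth profiles
# ---------------------------------------------------------------------------

DEPTH_BINS = ((0.0, 10.0), (10.0, 20.0), (20.0, 30.0))


def planktonic_fraction_profile(
    counts: pd.DataFrame,
    habitat: pd.Series,
    metadata: pd.DataFrame,
    sum_replicates: bool = True,
    bins: tuple[tuple[float, float], ...] = DEPTH_BINS,
) -> tuple[pd.Series, pd.Series]:
    """Per-sample planktonic read fraction and depth-binned mean fractions.

    ``counts`` is OTU x sample, ``habitat`` flags each OTU planktonic or
    benthic, and ``metadata`` supplies depth intervals. Replicates named
    ``<sample>.repK`` are summed before fractions (default). Samples whose
    layer midpoint falls in ``[lo, hi)`` contribute to that bin's mean;
    zero-total samples are excluded with a warning.
    """
    plank = counts.loc[habitat == "planktonic"].sum(axis=0)
    total = counts.sum(axis=0)
    mid = (
        metadata["depth_cm_top"].astype(float) + metadata["depth_cm_bottom"].astype(float)
    ) / 2.0
    if sum_replicates:
        base = pd.Series(counts.columns, index=counts.columns).str.replace(
            r"\.rep\d+$", "", regex=True
        )
        plank = plank.groupby(base).sum()
        total = total.groupby(base).sum()
        mid = mid.groupby(metadata.index.str.replace(r"\.rep\d+$", "", regex=True)).first()
    zero = total == 0
    if zero.any():
        logger.warning("excluding zero-total samples: %s", list(total.index[zero]))
    fractions = (plank[~zero] / total[~zero]).rename("planktonic_fraction")
    mid = mid.reindex(fractions.index)
    summaries = {}
    for lo, hi in bins:
        sel = (mid >= lo) & (mid < hi)
        summaries[f"[{lo:g},{hi:g})"] = float(fractions[sel].mean()) if sel.any() else np.nan
    return fractions, pd.Series(summaries, name="mean_planktonic_fraction")


# ---------------------------------------------------------------------------
# congruence
# ---------------------------------------------------------------------------


def congruence_report(
    fossil: pd.DataFrame,
    molecular: pd.DataFrame,
    metadata: pd.DataFrame,
    spinose_taxa: list[str] | None = None,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, object]:
    """Compare fossil and metabarcode assemblages over their shared samples.

    Spinose taxa (primer dropouts, absent from the molecular data by
    construction) are removed from the fossil table for comparability.
    Returns per-source PCoA, dispersion and PERMANOVA p-values by site and by
    zone, and the Mantel correlation between the two Bray-Curtis matrices.
    """
    shared = fossil.index.intersection(molecular.index)
    if len(shared) < 3:
        raise ValueError("need at least 3 shared samples")
    fossil = fossil.loc[shared]
    molecular = molecular.loc[shared]
    if spinose_taxa:
        fossil = fossil.drop(columns=[c for c in spinose_taxa if c in fossil.columns])

    report: dict[str, object] = {}
    dms = {}
    for name, table in (("fossil", fossil), ("molecular", molecular)):
        dm = bray_curtis(table)
        dms[name] = dm
        report[f"{name}_pcoa"] = pcoa(dm)
        for grouping in ("site", "zone"):
            labels = metadata.loc[shared, grouping]
            if labels.nunique() < 2:
                continue
            report[f"{name}_dispersion_{grouping}"] = dispersion_test(
                dm, labels, n_perm=n_perm, seed=seed
            )
            report[f"{name}_permanova_{grouping}"] = permanova(
                dm, labels, n_perm=n_perm, seed=seed
            )
    report["mantel"] = mantel(dms["fossil"], dms["molecular"], n_perm=n_perm, seed=seed)
    return report
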