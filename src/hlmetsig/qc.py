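"""Metabolite-matrix preprocessing: pooled-reference standardization,
filtering, rank-based inverse-normal transformation, and iterative
random-forest imputation.

The order used by the pipeline is: standardize -> filter metabolites ->
impute missing values -> inverse-normal transform. Filtering happens before
imputation so that no column with a high missing fraction is ever imputed;
the transform is applied to the completed matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.ensemble import RandomForestRegressor

from ._containers import MetaboliteMatrix, ValidationError

#: Metabolites with a missing fraction strictly above this are dropped.
METABOLITE_MISSING_CUTOFF = 0.20


def standardize_to_pooled_reference(raw: MetaboliteMatrix) -> MetaboliteMatrix:
    """Drift-correct abundances against interleaved pooled references.

    Each participant value is divided by the value of the *nearest* pooled
    reference in injection order (ties broken toward the earlier injection)
    and multiplied by the median of that metabolite over all pooled
    references. References with a missing or zero value for a metabolite
    are skipped in favour of the next nearest; a metabolite with no usable
    reference at all is flagged in ``unusable`` and left unstandardized.

    Returns a participants-only matrix (reference rows are consumed).
    """
    ref_rows = np.flatnonzero(raw.is_reference)
    if len(ref_rows) == 0:
        raise ValidationError("no pooled-reference records present")
    part_rows = np.flatnonzero(~raw.is_reference)
    vals = raw.values.to_numpy(dtype=float)
    ref_pos = raw.run_order[ref_rows].astype(float)
    part_pos = raw.run_order[part_rows].astype(float)

    ref_vals = vals[ref_rows]  # (n_ref, p)
    with warnings.catch_warnings():
        # a metabolite with no usable reference yields an all-NaN slice here;
        # it is flagged unusable below
        warnings.simplefilter("ignore", RuntimeWarning)
        medians = np.nanmedian(np.where(ref_vals == 0, np.nan, ref_vals), axis=0)

    # rank references by |distance|, earlier wins ties
    dist = np.abs(part_pos[:, None] - ref_pos[None, :])
    order = np.lexsort((ref_pos[None, :].repeat(len(part_pos), 0), dist), axis=1)

    out = np.empty((len(part_rows), vals.shape[1]))
    unusable: list[str] = []
    for j in range(vals.shape[1]):
        ref_ok = np.isfinite(ref_vals[:, j]) & (ref_vals[:, j] != 0)
        if not ref_ok.any() or not np.isfinite(medians[j]):
            unusable.append(raw.values.columns[j])
            out[:, j] = vals[part_rows, j]
            continue
        # first usable reference in nearest-first order, per participant
        ok_sorted = ref_ok[order]  # (n_part, n_ref)
        first = np.argmax(ok_sorted, axis=1)
        chosen = order[np.arange(len(part_rows)), first]
        denom = ref_vals[chosen, j]
        out[:, j] = vals[part_rows, j] / denom * medians[j]

    vdf = pd.DataFrame(out, columns=raw.values.columns,
                       index=raw.values.index[part_rows])
    return MetaboliteMatrix(
        values=vdf,
        meta=raw.meta.copy(),
        run_order=raw.run_order[part_rows],
        is_reference=np.zeros(len(part_rows), dtype=bool),
        unusable=sorted(set(raw.unusable) | set(unusable)),
    )


def filter_metabolites(
    m: MetaboliteMatrix,
    max_missing: float = METABOLITE_MISSING_CUTOFF,
    drop_internal_standards: bool = True,
) -> tuple[MetaboliteMatrix, dict[str, int]]:
    """Drop internal standards, then metabolites missing in > ``max_missing``
    of participants (strictly greater: a metabolite at exactly the cut-off
    is retained). Survivor order is preserved.

    Returns the filtered matrix and a QC log of counts removed per rule.
    """
    cols = list(m.values.columns)
    is_std = m.meta.loc[cols, "is_internal_standard"].to_numpy(dtype=bool)
    keep = ~is_std if drop_internal_standards else np.ones(len(cols), dtype=bool)
    n_std = int((~keep).sum())

    if len(m.values) and keep.any():
        frac = m.missing_fraction().to_numpy()
    else:
        frac = np.zeros(len(cols))
    high = keep & (frac > max_missing)
    n_high = int(high.sum())
    keep &= ~high

    kept_cols = [c for c, k in zip(cols, keep) if k]
    out = MetaboliteMatrix(
        values=m.values[kept_cols].copy(),
        meta=m.meta.loc[kept_cols].copy(),
        run_order=m.run_order.copy(),
        is_reference=m.is_reference.copy(),
        unusable=[c for c in m.unusable if c in kept_cols],
    )
    return out, {"internal_standard": n_std, "high_missing": n_high,
                 "retained": len(kept_cols)}


def inverse_normal_transform(column: np.ndarray | pd.Series) -> np.ndarray:
    """Blom rank-based inverse-normal transform of one metabolite column.

    Observed entries are replaced by ``Phi^-1((rank - 3/8) / (n_obs + 1/4))``
    with average ranks for ties; missing entries remain missing. A constant
    column maps all observed entries to the midpoint quantile (0) with a
    warning.
    """
    x = np.asarray(column, dtype=float)
    out = np.full_like(x, np.nan)
    obs = np.isfinite(x)
    n_obs = int(obs.sum())
    if n_obs < 2:
        raise ValidationError("inverse-normal transform needs >= 2 observed values")
    v = x[obs]
    if np.ptp(v) == 0:
        warnings.warn("constant column in inverse-normal transform; "
                      "mapping all observed entries to 0", stacklevel=2)
    ranks = rankdata(v, method="average")
    out[obs] = norm.ppf((ranks - 0.375) / (n_obs + 0.25))
    return out


def transform_matrix(m: MetaboliteMatrix) -> MetaboliteMatrix:
    """Apply the inverse-normal transform to every metabolite column."""
    out = m.copy()
    pv = out.participant_values()
    transformed = np.column_stack([inverse_normal_transform(pv[c]) for c in pv.columns])
    out.values.loc[~out.is_reference, :] = transformed
    return out


def impute_missing(
    m: MetaboliteMatrix,
    n_trees: int = 100,
    max_iter: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
) -> MetaboliteMatrix:
    """Iterative random-forest imputation of missing metabolite values.

    Missing entries are initialized with column means; columns are then
    visited in order of increasing missingness, each regressed on all other
    columns with a random-forest and its missing entries replaced by the
    forest's predictions. Iteration stops when the relative change in the
    imputed values rises (the previous iterate is returned, the usual
    early-stopping rule for this scheme), when it falls below ``tol``, or at
    ``max_iter``. Observed entries are never altered. Deterministic given
    ``seed``.
    """
    out = m.copy()
    pv = out.participant_values()
    X = pv.to_numpy(dtype=float)
    miss = ~np.isfinite(X)
    if not miss.any():
        return out
    if miss.all(axis=0).any():
        bad = pv.columns[miss.all(axis=0)][0]
        raise ValidationError(f"column {bad!r} is fully missing; filter first")

    col_means = np.nanmean(X, axis=0)
    Ximp = np.where(miss, col_means[None, :], X)
    cols = np.argsort(miss.sum(axis=0))
    cols = cols[miss.sum(axis=0)[cols] > 0]

    rng = np.random.default_rng(seed)
    prev = Ximp.copy()
    prev_delta = np.inf
    for it in range(max_iter):
        rf_seed = int(rng.integers(0, 2**31 - 1))
        for j in cols:
            obs_j = ~miss[:, j]
            others = np.delete(np.arange(X.shape[1]), j)
            rf = RandomForestRegressor(
                n_estimators=n_trees, max_features="sqrt",
                random_state=rf_seed, n_jobs=1,
            )
            rf.fit(Ximp[np.ix_(obs_j, others)], X[obs_j, j])
            Ximp[~obs_j, j] = rf.predict(Ximp[np.ix_(~obs_j, others)])
        num = float(((Ximp - prev)[miss] ** 2).sum())
        den = float((Ximp[miss] ** 2).sum())
        delta = num / den if den > 0 else 0.0
        if delta > prev_delta:
            Ximp = prev  # change rose: keep previous iterate
            break
        prev = Ximp.copy()
        if delta < tol:
            break
        prev_delta = delta

    filled = pv.copy()
    filled.loc[:, :] = Ximp
    out.values.loc[~out.is_reference, :] = filled
    return out


def qc_pipeline(
    m: MetaboliteMatrix,
    max_missing: float = METABOLITE_MISSING_CUTOFF,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
    standardize: bool = True,
) -> tuple[MetaboliteMatrix, dict[str, int]]:
    """Full preprocessing chain: standardize, filter, impute, transform."""
    if standardize and m.is_reference.any():
        m = standardize_to_pooled_reference(m)
    m, log = filter_metabolites(m, max_missing=max_missing)
    m = impute_missing(m, n_trees=n_trees, max_iter=max_iter, seed=seed)
    m = transform_matrix(m)
    return m, log
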