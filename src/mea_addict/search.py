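"""Exhaustive parameter-subset search with PCA and a phase-shift criterion.

The screening question is which of the 13 analytical parameters carry
chronic-exposure information that is specific to addictive compounds.  The
search enumerates every subset of ≥2 parameters (8178 subsets for 13), fits
a standardized PCA per subset on the vehicle-normalised well-level rows,
and tests, per compound, whether the before- vs after-chronic score clouds
differ on the first two components (two-group Wilks/Hotelling test on
per-well mean scores — wells are the independent replicates; the dose rows
of one well share its vehicle-step divisor and are therefore correlated,
so pooling them directly would overstate the evidence).  A
subset *qualifies* when every addictive compound shifts significantly while
no non-addictive compound (vehicle included) does; among qualifying subsets
the one whose worst addictive-compound p-value is smallest is selected and
its PCA model is refitted for downstream classification.

All arithmetic is deterministic: no randomness enters the search, subsets
are enumerated in a fixed order (by size, then lexicographically), and PCA
component signs follow a fixed convention (the largest-magnitude loading of
each component is positive).
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special

from .bursts import PARAMETERS, FeatureTable

__all__ = [
    "PCAModel",
    "SubsetEvaluation",
    "SearchResult",
    "SelectionResult",
    "enumerate_subsets",
    "cumulative_contribution",
    "fit_pca",
    "evaluate_subset",
    "search_subsets",
    "select_parameter_set",
]

ADDICTIVE = "addictive"
NON_ADDICTIVE = "non_addictive"
VEHICLE = "vehicle"


def enumerate_subsets(n_parameters: int = 13, min_size: int = 2) -> list[tuple[int, ...]]:
    """All index subsets of size ≥ ``min_size``, by size then lexicographic.

    For ``min_size`` 2 the count is 2**n − 1 − n (8178 for n = 13).
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if min_size > n_parameters:
        warnings.warn("min_size exceeds n_parameters; no subsets", stacklevel=2)
        return []
    out: list[tuple[int, ...]] = []
    for k in range(min_size, n_parameters + 1):
        out.extend(itertools.combinations(range(n_parameters), k))
    return out


def cumulative_contribution(ratios: Sequence[float], n_components: int = 2) -> float:
    """Cumulative contribution rate (%) of the first ``n_components``."""
    return float(np.sum(np.asarray(ratios, dtype=float)[:n_components]))


@dataclass
class PCAModel:
    """Standardized PCA fitted on one parameter subset.

    Columns are z-scored (sample SD) before the eigendecomposition of their
    correlation matrix; components are ordered by decreasing variance and
    sign-fixed so that each component's largest-magnitude loading is
    positive.  ``explained_variance_ratio`` is in percent and sums to 100
    over all components.
    """

    subset: tuple[str, ...]
    column_means: np.ndarray
    column_sds: np.ndarray
    loadings: np.ndarray  # (n_params, n_components)
    explained_variance_ratio: np.ndarray  # percent, per component

    def transform(self, X: np.ndarray, n_components: int | None = None) -> np.ndarray:
        """Project raw-scale rows onto the components."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        Z = (X - self.column_means) / self.column_sds
        W = self.loadings if n_components is None else self.loadings[:, :n_components]
        return Z @ W

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "subset": list(self.subset),
            "column_means": self.column_means.tolist(),
            "column_sds": self.column_sds.tolist(),
            "loadings": self.loadings.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "PCAModel":
        d = json.loads(Path(path).read_text())
        return cls(
            subset=tuple(d["subset"]),
            column_means=np.asarray(d["column_means"], dtype=float),
            column_sds=np.asarray(d["column_sds"], dtype=float),
            loadings=np.asarray(d["loadings"], dtype=float),
            explained_variance_ratio=np.asarray(d["explained_variance_ratio"], dtype=float),
        )


@dataclass
class SubsetEvaluation:
    """Outcome of the qualification test for one parameter subset."""

    subset: tuple[str, ...]
    p_by_compound: dict[str, float]
    qualifies: bool
    score: float  # selection key: mean log p of per-concentration phase tests
    # across addictive compounds (lower = more significant)
    reason: str | None = None  # why disqualified, when not by p-values alone


@dataclass
class SearchResult:
    """All subset evaluations of one exhaustive search."""

    evaluations: list[SubsetEvaluation]
    alpha: float
    labels: dict[str, str]

    @property
    def qualifying(self) -> list[SubsetEvaluation]:
        return [e for e in self.evaluations if e.qualifies]

    def report(self) -> pd.DataFrame:
        compounds = sorted(self.labels)
        rows = []
        for e in self.evaluations:
            row = {
                "subset": "+".join(e.subset),
                "size": len(e.subset),
                "qualifies": e.qualifies,
                "score": e.score,
                "reason": e.reason or "",
            }
            for c in compounds:
                row[f"p_{c}"] = e.p_by_compound.get(c, np.nan)
            rows.append(row)
        return pd.DataFrame(rows)


@dataclass
class SelectionResult:
    """The most significant parameter set, or an explicit 'none found'."""

    found: bool
    best: SubsetEvaluation | None = None
    model: PCAModel | None = None
    n_qualifying: int = 0


# ---------------------------------------------------------------------------
# internal: prepared matrix view of a feature table
# ---------------------------------------------------------------------------


class _SearchData:
    """Cached numeric view of a normalized feature table.

    Rows are the dose rows (baseline rows are identically 100 after
    normalisation and carry no information).  Per row we keep a bitmask of
    missing parameters, a (compound, concentration, phase) group id for the
    completeness rule, and a (compound, phase) id for the phase test.
    """

    def __init__(self, table: FeatureTable, min_wells: int = 3):
        if not table.normalized:
            raise ValueError("subset search expects a vehicle-normalized table")
        df = table.dose_rows().reset_index(drop=True)
        if df.empty:
            raise ValueError("feature table has no dose rows")
        self.min_wells = min_wells
        self.X = df[list(PARAMETERS)].to_numpy(dtype=float)
        nan = np.isnan(self.X)
        self.patterns = (nan.astype(np.int64) << np.arange(len(PARAMETERS))).sum(axis=1)

        grp_keys = df[["compound", "concentration", "phase"]].apply(tuple, axis=1)
        self.gid, grp_uniques = pd.factorize(grp_keys)
        self.n_groups = int(self.gid.max()) + 1

        cp_keys = df[["compound", "phase"]].apply(tuple, axis=1)
        self.cpid, cp_uniques = pd.factorize(cp_keys)
        self.n_cp = len(cp_uniques)
        self.compounds = sorted(df["compound"].unique())
        from .recording import BEFORE, AFTER

        cp_index = {cp: i for i, cp in enumerate(cp_uniques)}
        self.phase_ids = {
            c: (cp_index.get((c, BEFORE), -1), cp_index.get((c, AFTER), -1))
            for c in self.compounds
        }

        # well × phase grouping for the phase test (one mean score per well)
        wp_keys = df[["compound", "phase", "well"]].apply(tuple, axis=1)
        self.wpid, wp_uniques = pd.factorize(wp_keys)
        self.n_wp = len(wp_uniques)
        self.wp_cp = np.array([cp_index[(c, p)] for (c, p, _w) in wp_uniques])

        # before/after group-id pairs per compound × concentration, for the
        # finer-grained selection score
        pair_index: dict[tuple[str, float], dict[str, int]] = {}
        for g, (comp, conc, phase) in enumerate(grp_uniques):
            pair_index.setdefault((comp, conc), {})[phase] = g
        self.conc_pairs: dict[str, list[tuple[int, int]]] = {c: [] for c in self.compounds}
        for (comp, _conc), phases in sorted(pair_index.items()):
            if BEFORE in phases and AFTER in phases:
                self.conc_pairs[comp].append((phases[BEFORE], phases[AFTER]))

    def valid_rows(self, cols: Sequence[int]) -> np.ndarray:
        smask = 0
        for c in cols:
            smask |= 1 << int(c)
        valid = (self.patterns & smask) == 0
        counts = np.bincount(self.gid, weights=valid, minlength=self.n_groups)
        return valid & (counts[self.gid] >= self.min_wells)


def _pca_from_matrix(Xv: np.ndarray, param_names: Sequence[str]) -> PCAModel:
    """Standardized PCA of a complete (no-NaN) matrix."""
    n, k = Xv.shape
    if n < 3:
        raise ValueError("need at least 3 complete rows for PCA")
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant column(s): {[param_names[i] for i in const]}")
    Z = (Xv - mu) / sd
    C = Z.T @ Z / (n - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1]
    w, V = np.clip(w[order], 0.0, None), V[:, order]
    for j in range(k):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    evr = 100.0 * w / w.sum()
    return PCAModel(
        subset=tuple(param_names),
        column_means=mu,
        column_sds=sd,
        loadings=V,
        explained_variance_ratio=evr,
    )


def fit_pca(table: FeatureTable, subset: Sequence[str], min_wells: int = 3) -> PCAModel:
    """Fit a standardized PCA on one parameter subset of a normalized table.

    Rows incomplete on the subset are dropped; (compound, concentration,
    phase) groups with fewer than ``min_wells`` complete rows are excluded.
    A constant column raises an error naming the parameter.
    """
    if len(subset) < 2:
        raise ValueError("subset needs at least 2 parameters")
    cols = [PARAMETERS.index(p) for p in subset]
    data = _SearchData(table, min_wells=min_wells)
    valid = data.valid_rows(cols)
    Xv = data.X[np.flatnonzero(valid)][:, cols]
    return _pca_from_matrix(Xv, list(subset))


def _group_moments(group_ids, v1, v2, n_groups):
    """Counts plus first and second moments of 2-D scores per group."""
    cnt = np.bincount(group_ids, minlength=n_groups)
    s1 = np.bincount(group_ids, weights=v1, minlength=n_groups)
    s2 = np.bincount(group_ids, weights=v2, minlength=n_groups)
    q11 = np.bincount(group_ids, weights=v1 * v1, minlength=n_groups)
    q12 = np.bincount(group_ids, weights=v1 * v2, minlength=n_groups)
    q22 = np.bincount(group_ids, weights=v2 * v2, minlength=n_groups)
    return cnt, s1, s2, q11, q12, q22


def _moment_hotelling_p(mom, ia: int, ib: int) -> float:
    """Two-group Hotelling p on 2-D scores from per-group moments.

    Closed-form 2×2 pooled-covariance inverse; a non-positive determinant
    gets a tiny ridge.  Matches :func:`mea_addict.stats.manova_two_group`.
    """
    cnt, s1, s2, q11, q12, q22 = mom
    na, nb = int(cnt[ia]), int(cnt[ib])
    m1a, m2a = s1[ia] / na, s2[ia] / na
    m1b, m2b = s1[ib] / nb, s2[ib] / nb
    d1, d2 = m1a - m1b, m2a - m2b
    dof = na + nb - 2
    sxx = (q11[ia] - na * m1a * m1a + q11[ib] - nb * m1b * m1b) / dof
    sxy = (q12[ia] - na * m1a * m2a + q12[ib] - nb * m1b * m2b) / dof
    syy = (q22[ia] - na * m2a * m2a + q22[ib] - nb * m2b * m2b) / dof
    det = sxx * syy - sxy * sxy
    if det <= 0 or not np.isfinite(det):
        scale = 0.5 * (sxx + syy) if (sxx + syy) > 0 else 1.0
        sxx += 1e-8 * scale
        syy += 1e-8 * scale
        det = sxx * syy - sxy * sxy
    quad = (d1 * d1 * syy - 2.0 * d1 * d2 * sxy + d2 * d2 * sxx) / det
    t2 = na * nb / (na + nb) * quad
    df2 = na + nb - 3
    f_stat = df2 / (2.0 * dof) * t2
    return float(special.fdtrc(2.0, float(df2), max(f_stat, 0.0)))


def _eval_one(
    data: _SearchData,
    cols: tuple[int, ...],
    labels: Mapping[str, str],
    alpha: float,
    n_components: int = 2,
) -> SubsetEvaluation:
    """Evaluate one subset: PCA fit, per-compound phase test, qualification."""
    names = tuple(PARAMETERS[c] for c in cols)
    valid = data.valid_rows(cols)
    nv = int(valid.sum())
    p_by: dict[str, float] = {}
    if nv < 3:
        return SubsetEvaluation(names, p_by, False, math.inf, reason="too_few_rows")

    idx = np.flatnonzero(valid)
    Xv = data.X[idx][:, cols]
    mu = Xv.mean(axis=0)
    sd = Xv.std(axis=0, ddof=1)
    if np.any(sd == 0):
        return SubsetEvaluation(names, p_by, False, math.inf, reason="constant_column")
    Z = (Xv - mu) / sd
    C = Z.T @ Z / (nv - 1)
    w, V = np.linalg.eigh(C)
    order = np.argsort(w)[::-1][:n_components]
    W = V[:, order]
    for j in range(W.shape[1]):
        i = int(np.argmax(np.abs(W[:, j])))
        if W[i, j] < 0:
            W[:, j] = -W[:, j]
    scores = Z @ W  # (nv, 2)

    # one mean score per well × phase: wells are the independent replicates
    wp = data.wpid[idx]
    cw = np.bincount(wp, minlength=data.n_wp)
    has = cw > 0
    u1 = np.bincount(wp, weights=scores[:, 0], minlength=data.n_wp)[has] / cw[has]
    u2 = np.bincount(wp, weights=scores[:, 1], minlength=data.n_wp)[has] / cw[has]
    cp_mom = _group_moments(data.wp_cp[has], u1, u2, data.n_cp)

    skipped = []
    for comp in data.compounds:
        ia, ib = data.phase_ids[comp]
        if ia < 0 or ib < 0 or cp_mom[0][ia] < 3 or cp_mom[0][ib] < 3:
            skipped.append(comp)
            continue
        p_by[comp] = _moment_hotelling_p(cp_mom, ia, ib)

    addictive = [c for c in data.compounds if labels.get(c) == ADDICTIVE]
    nulls = [c for c in data.compounds if labels.get(c) in (NON_ADDICTIVE, VEHICLE)]
    if skipped:
        return SubsetEvaluation(
            names, p_by, False, math.inf,
            reason="compound_skipped:" + ",".join(skipped),
        )
    qualifies = bool(addictive) and all(p_by[c] < alpha for c in addictive) and all(
        p_by[c] >= alpha for c in nulls
    )

    # Selection score: mean log p of the per-concentration before/after
    # tests over the addictive compounds.  Finer-grained than the pooled
    # qualification test, it averages the covariance-estimation noise of
    # many small tests and ranks candidate subsets far more stably.
    score = math.inf
    if qualifies:
        g_mom = _group_moments(data.gid[idx], scores[:, 0], scores[:, 1], data.n_groups)
        logs = []
        for comp in addictive:
            for ga, gb in data.conc_pairs[comp]:
                if g_mom[0][ga] >= 3 and g_mom[0][gb] >= 3:
                    logs.append(math.log(max(_moment_hotelling_p(g_mom, ga, gb), 1e-300)))
        score = float(np.mean(logs)) if logs else math.inf
    return SubsetEvaluation(names, p_by, qualifies, score, reason=None)


def evaluate_subset(
    subset: Sequence[str],
    table: FeatureTable,
    labels: Mapping[str, str],
    alpha: float = 0.05,
    min_wells: int = 3,
) -> SubsetEvaluation:
    """Evaluate a single named parameter subset against the design labels.

    ``labels`` maps each compound to ``"addictive"``, ``"non_addictive"``
    or ``"vehicle"``.  The phase test pools all concentrations of a
    compound and compares before- vs after-chronic per-well mean scores
    on PC1/PC2 (one observation per well per phase).
    """
    cols = tuple(PARAMETERS.index(p) for p in subset)
    data = _SearchData(table, min_wells=min_wells)
    return _eval_one(data, cols, labels, alpha)


def search_subsets(
    table: FeatureTable,
    labels: Mapping[str, str],
    min_size: int = 2,
    alpha: float = 0.05,
    min_wells: int = 3,
) -> SearchResult:
    """Exhaustively evaluate every parameter subset of size ≥ ``min_size``."""
    data = _SearchData(table, min_wells=min_wells)
    evaluations = [
        _eval_one(data, cols, labels, alpha)
        for cols in enumerate_subsets(len(PARAMETERS), min_size)
    ]
    return SearchResult(evaluations=evaluations, alpha=alpha, labels=dict(labels))


def select_parameter_set(
    evaluations: Sequence[SubsetEvaluation] | SearchResult,
    table: FeatureTable,
    min_wells: int = 3,
) -> SelectionResult:
    """Pick the qualifying subset with the smallest selection score.

    The score of a subset is the mean log p of its per-concentration
    before/after tests over the addictive compounds, so minimising it
    selects the set on which the addictive shift is most consistently
    significant.  Ties break toward the smaller subset, then
    lexicographically.  Returns an explicit
    "not found" result (not an exception) when nothing qualifies; on
    success the model is refitted on the winning subset for reuse.
    """
    if isinstance(evaluations, SearchResult):
        evaluations = evaluations.evaluations
    if not evaluations:
        raise ValueError("no evaluations given")
    qualifying = [e for e in evaluations if e.qualifies]
    if not qualifying:
        return SelectionResult(found=False, n_qualifying=0)
    best = min(qualifying, key=lambda e: (e.score, len(e.subset), e.subset))
    model = fit_pca(table, best.subset, min_wells=min_wells)
    return SelectionResult(found=True, best=best, model=model, n_qualifying=len(qualifying))
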