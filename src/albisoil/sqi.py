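"""Minimum-Data-Set soil quality index.

The index condenses a Total Data Set (TDS) of soil indicators into a
Minimum Data Set (MDS) and a single score per sample:

1. PCA of the Pearson correlation matrix of the indicators; components with
   eigenvalue >= 1 are retained (Kaiser rule).
2. Indicators are grouped by the retained component on which they load at
   |loading| >= 0.5 (multi-assignments and sub-threshold indicators go to
   their max-|loading| component).
3. Each indicator's Norm value N_i = sqrt(sum_j u_ij^2 * e_j) over retained
   components j measures its total explanatory power; within each group,
   indicators within 10% of the group maximum Norm survive.
4. Within a group, a significantly correlated survivor pair (Pearson, p
   below ``alpha``) keeps only its higher-Norm member.
5. The survivors' union is the MDS. Each MDS indicator is scored by a
   linear min-max membership F(X) in [0, 1] (direction-aware) and weighted
   by its communality over the retained components, renormalized to sum to
   one; SQI = sum_i W_i * F(X_i).

Loadings here are indicator-component correlations (eigenvector element x
sqrt(eigenvalue)), the convention under which both the |0.5| grouping
threshold and the Norm formula are standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateDataError, ValidationError
from .soil_tables import IndicatorTable

__all__ = [
    "PcaResult",
    "MdsSelection",
    "SqiResult",
    "pca_correlation",
    "norm_values",
    "select_mds",
    "membership",
    "compute_sqi",
]


@dataclass
class PcaResult:
    """Correlation-matrix PCA: eigenvalues (descending), loadings, Kaiser cut."""

    eigenvalues: np.ndarray
    loadings: pd.DataFrame  # indicators x PC1..PCp, = eigvec * sqrt(eigval)
    retained_k: int

    @property
    def indicator_names(self) -> list[str]:
        return [str(i) for i in self.loadings.index]

    def communalities(self) -> pd.Series:
        """Sum of squared loadings over the retained components."""
        u = self.loadings.iloc[:, : self.retained_k].to_numpy()
        return pd.Series((u**2).sum(axis=1), index=self.loadings.index)


@dataclass
class MdsSelection:
    """Outcome of the MDS selection with a full audit trail."""

    groups: dict[int, list[str]]  # retained PC index (0-based) -> indicators
    norms: pd.Series
    survivors_norm: list[str]
    final_set: list[str]
    audit_log: list[dict] = field(default_factory=list)
    pca: PcaResult | None = None


@dataclass
class SqiResult:
    memberships: pd.DataFrame  # samples x MDS indicators, in [0, 1]
    weights: pd.Series         # per MDS indicator, sums to 1
    sqi: pd.Series             # per sample
    treatment_means: pd.Series
    percent_change_vs_control: pd.Series


def pca_correlation(table: IndicatorTable) -> PcaResult:
    """Eigen-decompose the Pearson correlation matrix of the indicators.

    Loadings are signed so each component's largest-|loading| indicator
    loads positively (canonical sign); eigenvalues are clipped at zero
    against roundoff. Requires >= 3 samples and no constant indicator.
    """
    x = table.values
    n, p = x.shape
    if n < 3:
        raise ValidationError(f"correlation PCA needs >= 3 samples, got {n}")
    sd = x.std(axis=0, ddof=1)
    flat = [table.indicator_names[i] for i in np.flatnonzero(sd == 0)]
    if flat:
        raise DegenerateDataError(f"constant indicator(s): {flat}")

    corr = np.corrcoef(x, rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]

    loadings = eigvec * np.sqrt(eigval)
    for j in range(p):
        i_star = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i_star, j] < 0:
            loadings[:, j] = -loadings[:, j]

    retained = int(np.sum(eigval >= 1.0))
    if retained == 0:
        warnings.warn(
            "no eigenvalue >= 1; falling back to retaining PC1 only",
            stacklevel=2,
        )
        retained = 1
    frame = pd.DataFrame(
        loadings,
        index=table.indicator_names,
        columns=[f"PC{j + 1}" for j in range(p)],
    )
    return PcaResult(eigenvalues=eigval, loadings=frame, retained_k=retained)


def norm_values(pca: PcaResult) -> pd.Series:
    """Norm value per indicator: sqrt(sum over retained PCs of u^2 * e)."""
    k = pca.retained_k
    u = pca.loadings.iloc[:, :k].to_numpy()
    e = pca.eigenvalues[:k]
    return pd.Series(np.sqrt((u**2 * e).sum(axis=1)), index=pca.loadings.index)


def _pearson_p(r: float, n: int) -> float:
    """Two-sided p for a Pearson r via the t-transform with n-2 df."""
    r = min(max(r, -1.0), 1.0)
    if abs(r) >= 1.0:
        return 0.0
    t = abs(r) * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * sps.t.sf(t, n - 2))


def select_mds(table: IndicatorTable, alpha: float = 0.01) -> MdsSelection:
    """Apply the full MDS selection to ``table``; see the module docstring.

    Determinism: ties in group assignment and max-Norm comparisons are
    broken by original column order, and every drop is recorded in
    ``audit_log`` with the rule that triggered it.
    """
    pca = pca_correlation(table)
    names = pca.indicator_names
    k = pca.retained_k
    u = pca.loadings.iloc[:, :k].to_numpy()
    audit: list[dict] = []
    audit.append(
        {
            "rule": "retain_components",
            "detail": f"{k} component(s) with eigenvalue >= 1",
            "eigenvalues": [float(e) for e in pca.eigenvalues],
        }
    )

    groups: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        absrow = np.abs(u[i])
        hits = np.flatnonzero(absrow >= 0.5)
        if len(hits) == 0:
            pc = int(np.argmax(absrow))
            audit.append(
                {"rule": "assign_below_threshold", "indicator": name, "component": pc + 1}
            )
        elif len(hits) > 1:
            pc = int(hits[np.argmax(absrow[hits])])
            audit.append(
                {"rule": "resolve_multi_assignment", "indicator": name, "component": pc + 1}
            )
        else:
            pc = int(hits[0])
        groups.setdefault(pc, []).append(name)

    norms = norm_values(pca)
    survivors: list[str] = []
    final: list[str] = []
    n = table.n_samples
    corr = np.corrcoef(table.values, rowvar=False)
    idx = {name: i for i, name in enumerate(names)}

    for pc in sorted(groups):
        members = groups[pc]
        gmax = max(norms[m] for m in members)
        kept = []
        for m in members:
            if norms[m] >= 0.9 * gmax:
                kept.append(m)
            else:
                audit.append(
                    {
                        "rule": "norm_below_90pct_of_group_max",
                        "indicator": m,
                        "norm": float(norms[m]),
                        "group_max": float(gmax),
                    }
                )
        survivors.extend(kept)

        # correlation pruning, greedy in descending Norm (column order on ties)
        ranked = sorted(kept, key=lambda m: (-norms[m], idx[m]))
        chosen: list[str] = []
        for m in ranked:
            clash = None
            for c in chosen:
                r = corr[idx[m], idx[c]]
                if _pearson_p(r, n) < alpha:
                    clash = (c, float(r))
                    break
            if clash is None:
                chosen.append(m)
            else:
                audit.append(
                    {
                        "rule": "correlated_with_higher_norm",
                        "indicator": m,
                        "kept": clash[0],
                        "r": clash[1],
                        "alpha": alpha,
                    }
                )
        final.extend(chosen)

    survivors = [m for m in names if m in survivors]
    final = [m for m in names if m in final]
    if not final:  # unreachable: each group keeps its max-Norm member
        raise DegenerateDataError("MDS selection produced an empty set")
    return MdsSelection(
        groups=groups,
        norms=norms,
        survivors_norm=survivors,
        final_set=final,
        audit_log=audit,
        pca=pca,
    )


def membership(value, xmin: float, xmax: float, direction: str = "ascending"):
    """Linear min-max membership in [0, 1]; out-of-range values are clipped."""
    if xmax <= xmin:
        raise DegenerateDataError(f"degenerate range: xmin={xmin}, xmax={xmax}")
    if direction not in ("ascending", "descending"):
        raise ValidationError(f"direction must be ascending/descending, got {direction!r}")
    f = np.clip((np.asarray(value, dtype=float) - xmin) / (xmax - xmin), 0.0, 1.0)
    if direction == "descending":
        f = 1.0 - f
    return float(f) if np.isscalar(value) else f


def compute_sqi(table: IndicatorTable, selection: MdsSelection) -> SqiResult:
    """Score every sample: SQI = sum over MDS indicators of W_i * F(X_i).

    Weights are communalities over the retained components, renormalized
    over the final set; memberships use each indicator's observed min/max
    and its configured direction.
    """
    pca = selection.pca if selection.pca is not None else pca_correlation(table)
    final = selection.final_set
    missing = [m for m in final if m not in table.indicator_names]
    if missing:
        raise ValidationError(f"selection refers to absent indicator(s): {missing}")

    comm = pca.communalities().loc[final]
    weights = comm / comm.sum()

    members = {}
    for name in final:
        col = table.data[name].to_numpy()
        xmin, xmax = float(col.min()), float(col.max())
        if xmax <= xmin:
            raise DegenerateDataError(f"indicator {name!r} has xmin == xmax")
        members[name] = membership(col, xmin, xmax, table.directions[name])
    memberships = pd.DataFrame(members, index=table.data.index)[final]

    sqi = pd.Series(memberships.to_numpy() @ weights.to_numpy(), index=table.data.index)
    tmeans = sqi.groupby(table.treatments).mean()
    order = [t for t in table.design.treatments if t in tmeans.index]
    tmeans = tmeans.loc[order]
    control = table.design.control
    pct = 100.0 * (tmeans - tmeans[control]) / tmeans[control]
    return SqiResult(
        memberships=memberships,
        weights=weights,
        sqi=sqi,
        treatment_means=tmeans,
        percent_change_vs_control=pct.drop(control),
    )
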