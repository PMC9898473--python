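"""Effect-size conversion and robust-variance-estimation contrasts.

Edge weights (partial correlations / standardized lag-1 coefficients) are
converted to Cohen's d via ``d = 2r / sqrt(1 - r^2)``.  Sets of dependent
edge effect sizes are compared with robust variance estimation (RVE):
weighted least squares of d on group indicators with a cluster-robust
(CR2) sandwich covariance and Satterthwaite degrees of freedom, the
standard machinery for correlated effect sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "cohens_d_from_r",
    "r_from_cohens_d",
    "var_d_from_var_r",
    "EffectRecord",
    "RVEResult",
    "mean_significant_d",
    "rve_contrast",
    "effect_records_from_edges",
]


def cohens_d_from_r(r: float) -> float:
    """Cohen's d equivalent of a (partial) correlation: ``2r/sqrt(1-r^2)``.

    Odd and strictly increasing on (-1, 1).
    """
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError(f"|r| must be < 1, got {r}")
    return 2.0 * r / np.sqrt(1.0 - r * r)


def r_from_cohens_d(d: float) -> float:
    """Inverse conversion: ``r = d / sqrt(d^2 + 4)``."""
    d = float(d)
    return d / np.sqrt(d * d + 4.0)


def var_d_from_var_r(r: float, var_r: float) -> float:
    """Delta-method sampling variance of d given the variance of r."""
    deriv = 2.0 * (1.0 - r * r) ** (-1.5)
    return float(deriv * deriv * var_r)


@dataclass
class EffectRecord:
    """One edge's effect size prepared for an RVE comparison."""

    network: str
    source: str
    target: str
    r: float
    d: float
    var_d: float
    cluster_id: str
    group_labels: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self):
        if abs(self.r) >= 1.0:
            raise ValueError("|r| must be < 1")
        if np.sign(self.d) != np.sign(self.r) and self.d != 0.0:
            raise ValueError("sign(d) must equal sign(r)")
        if self.var_d <= 0.0:
            raise ValueError("var_d must be positive")


@dataclass
class RVEResult:
    """One contrast from the RVE meta-regression."""

    name: str
    beta: float
    se_robust: float
    ci_low: float
    ci_high: float
    df: float
    n_clusters: int

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("need at least 2 clusters")
        if not self.ci_low < self.ci_high:
            raise ValueError("ci_low must be < ci_high")


def mean_significant_d(edges, network: str) -> float:
    """Arithmetic mean of |d| over the significant edges of one network.

    Raises rather than returning 0 when no edge survives triage, so an
    empty set cannot masquerade as a null average.
    """
    ds = [abs(e.cohens_d) for e in edges if e.network == network and e.significant]
    if not ds:
        raise ValueError(f"no significant edges in the {network!r} network")
    return float(np.mean(ds))


def _design_matrix(records, design):
    """Build intercept + indicator (+ interaction) columns from labels."""
    cols = ["intercept"]
    cols += list(design)
    X = np.ones((len(records), len(cols)))
    for c, name in enumerate(design, start=1):
        if ":" in name:
            a, b = name.split(":")
            vals = [
                float(rec.group_labels.get(a, False))
                * float(rec.group_labels.get(b, False))
                for rec in records
            ]
        else:
            vals = [float(rec.group_labels.get(name, False)) for rec in records]
        X[:, c] = vals
    return X, cols


def rve_contrast(
    records: list[EffectRecord],
    design: list[str] | str,
    level: float = 0.95,
    small_sample: bool = True,
) -> list[RVEResult]:
    """RVE meta-regression of d on group indicators.

    ``design`` lists the indicator names (keys of ``group_labels``;
    ``"a:b"`` adds an interaction), or one of the presets
    ``"vulnerability_vs_scar"`` / ``"somatic_by_proinflammatory"``.
    Weights are inverse-variance, averaged within cluster
    (``w = 1 / (k_j * mean var_d in cluster j)``); the covariance is the
    CR2-adjusted cluster sandwich with Satterthwaite df unless
    ``small_sample=False`` (plain CR0 with ``n_clusters - rank`` df).
    Returns one :class:`RVEResult` per non-intercept column.
    """
    if isinstance(design, str):
        design = {
            "vulnerability_vs_scar": ["vulnerability"],
            "somatic_by_proinflammatory": [
                "somatic_involved",
                "proinflammatory_involved",
                "somatic_involved:proinflammatory_involved",
            ],
        }.get(design, [design])
    clusters = {}
    for i, rec in enumerate(records):
        clusters.setdefault(rec.cluster_id, []).append(i)
    if len(clusters) < 2:
        raise ValueError("all records fall in one cluster; need >= 2 clusters")
    X, cols = _design_matrix(records, design)
    y = np.array([rec.d for rec in records])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns: those whose removal restores full rank
        bad = [
            cols[c]
            for c in range(X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, c, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    w = np.empty(len(records))
    for idx in clusters.values():
        vbar = np.mean([records[i].var_d for i in idx])
        w[idx] = 1.0 / (len(idx) * vbar)

    sw = np.sqrt(w)
    Xt = X * sw[:, None]
    yt = y * sw
    M = np.linalg.inv(Xt.T @ Xt)
    beta = M @ (Xt.T @ yt)
    resid = yt - Xt @ beta

    cluster_blocks = []
    for idx in clusters.values():
        Xj = Xt[idx]
        ej = resid[idx]
        if small_sample:
            Hj = Xj @ M @ Xj.T
            wv, V = np.linalg.eigh(np.eye(len(idx)) - Hj)
            inv_sqrt = np.where(wv > 1e-10, 1.0 / np.sqrt(np.maximum(wv, 1e-10)), 0.0)
            Aj = (V * inv_sqrt) @ V.T
        else:
            Aj = np.eye(len(idx))
        cluster_blocks.append((Xj, Aj, ej))

    meat = np.zeros((X.shape[1], X.shape[1]))
    for Xj, Aj, ej in cluster_blocks:
        gj = Xj.T @ (Aj @ ej)
        meat += np.outer(gj, gj)
    V = M @ meat @ M

    out = []
    for c, name in enumerate(cols):
        if c == 0:
            continue
        se = float(np.sqrt(max(V[c, c], 0.0)))
        ell = np.zeros(X.shape[1])
        ell[c] = 1.0
        if small_sample:
            qs = []
            for Xj, Aj, _ in cluster_blocks:
                a = Aj @ (Xj @ (M @ ell))
                qs.append(float(a @ a))
            qs = np.asarray(qs)
            denom = float(np.sum(qs**2))
            df = float(np.sum(qs) ** 2 / denom) if denom > 0 else len(clusters) - rank
        else:
            df = float(len(clusters) - rank)
        df = max(df, 1.0)
        tcrit = stats.t.ppf(0.5 + level / 2.0, df)
        out.append(
            RVEResult(
                name=name,
                beta=float(beta[c]),
                se_robust=se,
                ci_low=float(beta[c] - tcrit * se),
                ci_high=float(beta[c] + tcrit * se),
                df=df,
                n_clusters=len(clusters),
            )
        )
    return out


def effect_records_from_edges(
    edges,
    nodes,
    networks=("temporal",),
    significant_only: bool = True,
    proinflammatory: tuple[str, ...] = ("crp", "fbr"),
    somatic: tuple[str, ...] = ("som",),
) -> list[EffectRecord]:
    """Turn triaged edge estimates into RVE-ready effect records.

    Vulnerability edges run biomarker(t-1) -> symptom(t); scar edges run
    symptom(t-1) -> biomarker(t).  The cluster is the edge's biomarker node
    (effect sizes sharing a biomarker are correlated), falling back to the
    source node.  ``var_d`` is delta-method-propagated from the bootstrap
    variance of the edge weight.
    """
    roles = {nd.name: nd.role for nd in nodes}
    out = []
    for e in edges:
        if e.network not in networks:
            continue
        if significant_only and not e.significant:
            continue
        src_role = roles.get(e.source, "biomarker")
        tgt_role = roles.get(e.target, "biomarker")
        vulnerability = src_role == "biomarker" and tgt_role == "symptom"
        scar = src_role == "symptom" and tgt_role == "biomarker"
        if e.network == "temporal" and not (vulnerability or scar):
            continue
        biomarker_node = e.source if src_role == "biomarker" else (
            e.target if tgt_role == "biomarker" else e.source
        )
        r = float(np.clip(e.weight, -0.999, 0.999))
        var_r = max(((e.ci_high - e.ci_low) / (2.0 * 1.959964)) ** 2, 1e-8)
        out.append(
            EffectRecord(
                network=e.network,
                source=e.source,
                target=e.target,
                r=r,
                d=cohens_d_from_r(r),
                var_d=var_d_from_var_r(r, var_r),
                cluster_id=biomarker_node,
                group_labels={
                    "vulnerability": vulnerability,
                    "scar": scar,
                    "somatic_involved": e.source in somatic or e.target in somatic,
                    "proinflammatory_involved": (
                        e.source in proinflammatory or e.target in proinflammatory
                    ),
                },
            )
        )
    return out
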