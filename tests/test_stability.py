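"""Bootstrap accuracy/stability summaries and the three-part triage."""

import dataclasses

import numpy as np
import pytest

from clpn import (
    EdgeEstimate,
    bootstrap,
    ci_accuracy_report,
    simulate,
    stability_report,
    summarize_edges,
)
from clpn.cohort import null_scenario, random_sparse_scenario
from clpn.effects import r_from_cohens_d
from clpn.stability import BootstrapArchive, edges_to_frame


class _StubFit:
    """Minimal stand-in for PanelGVARResults: networks + Wald p-values."""

    class _Nets:
        def __init__(self, mats):
            self.mats = mats

        def matrix(self, which):
            return self.mats[which]

    def __init__(self, mats, pvalues=None):
        self.networks = self._Nets(mats)
        self._pvalues = pvalues

    def edge_pvalues(self):
        if self._pvalues is None:
            raise ValueError("no parameter covariance available")
        return self._pvalues


def _archive(weights, p=2, n_reps=None, masks=None):
    n_reps = n_reps or weights["temporal"].shape[0]
    return BootstrapArchive(
        n_reps=n_reps,
        seed=0,
        node_names=[f"x{j + 1}" for j in range(p)],
        weights=weights,
        masks=masks or {},
    )


def test_percentile_ci_matches_interpolation_oracle():
    reps = np.arange(1, 1001) / 1000.0
    w = np.zeros((1000, 2, 2))
    w[:, 0, 1] = reps
    weights = {k: w.copy() for k in ("temporal", "contemporaneous", "between")}
    mats = {k: np.zeros((2, 2)) for k in weights}
    edges = summarize_edges(_archive(weights), _StubFit(mats), pvalue_method="bootstrap")
    edge = next(
        e for e in edges if e.network == "temporal" and e.source == "x2" and e.target == "x1"
    )

    # independent sort-and-interpolate oracle for the 2.5/97.5 percentiles
    def pct(sorted_x, q):
        h = (len(sorted_x) - 1) * q
        lo = int(np.floor(h))
        return sorted_x[lo] + (h - lo) * (sorted_x[min(lo + 1, len(sorted_x) - 1)] - sorted_x[lo])

    s = np.sort(reps)
    assert edge.ci_low == pytest.approx(pct(s, 0.025), abs=1e-12)
    assert edge.ci_high == pytest.approx(pct(s, 0.975), abs=1e-12)
    assert edge.ci_low == pytest.approx(0.025975, abs=1e-9)
    assert edge.ci_high == pytest.approx(0.975025, abs=1e-9)


def _triage_case(d_value):
    """One temporal edge with p = 0.0005, inclusion 0.62 and the given d."""
    p = 2
    r = r_from_cohens_d(d_value)
    w = np.zeros((100, p, p))
    w[:, 0, 1] = r
    weights = {k: w.copy() for k in ("temporal", "contemporaneous", "between")}
    m = np.zeros((100, p, p), dtype=bool)
    m[:62, 0, 1] = True
    masks = {k: m.copy() for k in ("temporal", "contemporaneous", "between")}
    mats = {k: np.zeros((p, p)) for k in weights}
    mats["temporal"][0, 1] = r
    pvals = {("temporal", 0, 1): 0.0005}
    edges = summarize_edges(_archive(weights, masks=masks), _StubFit(mats, pvals))
    return next(
        e for e in edges if e.network == "temporal" and e.source == "x2" and e.target == "x1"
    )


def test_triage_rule_applies():
    edge = _triage_case(0.15)
    assert edge.inclusion_freq == pytest.approx(0.62)
    assert edge.p_value == pytest.approx(0.0005)
    assert edge.cohens_d == pytest.approx(0.15, abs=1e-9)
    assert edge.significant


def test_triage_small_d_not_significant():
    edge = _triage_case(0.08)
    assert not edge.significant  # d below the 0.100 cut


def test_triage_monotone_in_thresholds():
    p = 2
    w = np.zeros((50, p, p))
    w[:, 0, 1] = 0.2
    weights = {k: w.copy() for k in ("temporal", "contemporaneous", "between")}
    m = np.zeros((50, p, p), dtype=bool)
    m[:30, 0, 1] = True
    masks = {k: m.copy() for k in ("temporal", "contemporaneous", "between")}
    mats = {k: np.zeros((p, p)) for k in weights}
    mats["temporal"][0, 1] = 0.2
    pvals = {("temporal", 0, 1): 0.0002}
    arch = _archive(weights, masks=masks)
    strict = summarize_edges(arch, _StubFit(mats, pvals))
    loose = summarize_edges(
        arch, _StubFit(mats, pvals),
        p_threshold=0.01, inclusion_threshold=0.3, d_threshold=0.05,
    )
    for e_strict, e_loose in zip(strict, loose):
        if e_strict.significant:
            assert e_loose.significant


def test_report_arithmetic():
    def edge(net, ci_low, incl):
        return EdgeEstimate(
            network=net, source="a", target="b", weight=0.5,
            ci_low=ci_low, ci_high=0.9, p_value=0.5,
            inclusion_freq=incl, cohens_d=0.1, significant=False,
        )

    edges = [edge("contemporaneous", 0.1, 1.0)] * 90 + [edge("contemporaneous", -0.1, 0.0)]
    assert ci_accuracy_report(edges)["contemporaneous"] == (90, 91, 98.9)
    edges = [edge("between", 0.1, 1.0)] * 88 + [edge("between", -0.1, 0.0)] * 3
    assert ci_accuracy_report(edges)["between"] == (88, 91, 96.7)
    edges = [edge("temporal", -1, 1.0)] * 129 + [edge("temporal", -1, 0.2)] * 67
    assert stability_report(edges)["temporal"] == (129, 196, 65.8)
    edges = [edge("contemporaneous", -1, 0.8)] * 54 + [edge("contemporaneous", -1, 0.1)] * 37
    assert stability_report(edges)["contemporaneous"] == (54, 91, 59.3)
    edges = [edge("between", -1, 0.2)] * 91
    assert stability_report(edges)["between"] == (0, 91, 0.0)
    assert ci_accuracy_report(edges)["between"] == (0, 91, 0.0)


def test_bootstrap_deterministic(null_data_small):
    a = bootstrap(null_data_small, n_reps=2, seed=12, select=False)
    b = bootstrap(null_data_small, n_reps=2, seed=12, select=False)
    for k in a.weights:
        assert np.array_equal(a.weights[k], b.weights[k])


def test_bootstrap_resampling_uniform():
    # the replicate index draw is i.i.d. uniform over persons: pooled over
    # seeds, person counts stay within chi-square bounds
    n = 10
    counts = np.zeros(n)
    draws = 0
    for seed in range(200):
        idx = np.random.default_rng(seed).integers(0, n, size=(1, n))
        counts += np.bincount(idx.ravel(), minlength=n)
        draws += n
    expected = draws / n
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    # chi-square(9) 0.999 quantile ~ 27.9
    assert chi2 < 27.9


def test_bootstrap_failure_cap(null_data_small, monkeypatch):
    import clpn.stability as stab

    def boom(*args, **kwargs):
        raise RuntimeError("solver exploded")

    monkeypatch.setattr(stab, "_networks_for_subset", boom)
    with pytest.raises(RuntimeError, match="replicates failed"):
        stab.bootstrap(null_data_small, n_reps=10, seed=1)


def test_ci_width_shrinks_with_n():
    widths = {}
    for n in (250, 1000):
        sc = dataclasses.replace(
            random_sparse_scenario(5, n_nodes=4, n_waves=4, seed=17), n_persons=n
        )
        data = simulate(sc)
        arch = bootstrap(data, n_reps=80, seed=2, select=False)
        w = arch.weights["temporal"]
        lo, hi = np.percentile(w, [2.5, 97.5], axis=0)
        widths[n] = float(np.mean(hi - lo))
    assert widths[1000] < widths[250]


def test_edges_to_frame_columns(null_data_small):
    arch = bootstrap(null_data_small, n_reps=5, seed=3, select=False)
    mats = {
        k: np.zeros((null_data_small.n_nodes, null_data_small.n_nodes))
        for k in ("temporal", "contemporaneous", "between")
    }
    edges = summarize_edges(arch, _StubFit(mats), pvalue_method="bootstrap")
    frame = edges_to_frame(edges)
    assert list(frame.columns) == [
        "network", "source", "target", "weight", "ci_low", "ci_high",
        "p", "inclusion", "d", "significant",
    ]
    p = null_data_small.n_nodes
    assert len(frame) == p * p + 2 * (p * (p - 1) // 2)


def test_archive_validation():
    with pytest.raises(ValueError, match="n_reps"):
        BootstrapArchive(
            n_reps=0, seed=0, node_names=["a"],
            weights={"temporal": np.zeros((1, 1, 1))},
        )
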