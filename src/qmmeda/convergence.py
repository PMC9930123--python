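"""QM-region-size convergence scans and snapshot-ensemble statistics.

A scan repeats the decomposition while growing the number of QM waters,
tracking each component's deviation from the largest-region reference;
the region is converged at the smallest size whose deviations — and
those of every larger sampled size — stay inside a ±tolerance band
(1 kcal/mol by default).  Ensemble statistics summarize a sample of
snapshot decompositions per component: mean, sample standard deviation
(n−1 denominator) and relative standard deviation 100·σ/|mean|.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .eda_core import EDAConfig, EDAResult, assemble_eda
from .systems_io import partition_closest_n, SolvatedSnapshot

__all__ = ["COMPONENTS", "ScanResult", "SampleStats", "NormalSummary",
           "run_scan", "converged_size", "sample_stats",
           "sample_mean_convergence", "scan_to_frame", "plot_deviations",
           "plot_normal_distributions"]

#: component labels tracked everywhere, in reporting order
COMPONENTS = ("ELE", "PAU", "POL", "TOT", "DISP", "IND")


@dataclass
class ScanResult:
    sizes: list
    results: dict                      # size -> EDAResult (or None on failure)
    reference_size: int
    deviations: dict                   # size -> {component: value or nan}
    failures: dict = field(default_factory=dict)   # size -> error message

    @property
    def missing_sizes(self):
        return [s for s in self.sizes if self.results.get(s) is None]

    def deviation_series(self, component):
        return {s: self.deviations[s][component] for s in self.sizes
                if s in self.deviations}


@dataclass
class SampleStats:
    """Per-component mean / sample sigma / RSTD for an ensemble."""

    table: pd.DataFrame   # index: component; columns mean, sigma, rstd
    n_samples: int
    sigma_convention: str = "sample (n-1 denominator)"

    def to_csv(self, path):
        out = self.table.copy()
        out.insert(0, "component", out.index)
        out["n"] = self.n_samples
        out.to_csv(path, index=False)


@dataclass
class NormalSummary:
    """Normal densities N(mean, sigma) per component for distribution plots."""

    parameters: dict      # component -> (mean, sigma)

    def pdf(self, component, x):
        mean, sigma = self.parameters[component]
        x = np.asarray(x, dtype=float)
        return np.exp(-0.5 * ((x - mean) / sigma) ** 2) \
            / (sigma * np.sqrt(2.0 * np.pi))

    @classmethod
    def from_stats(cls, stats: SampleStats):
        return cls({c: (float(stats.table.loc[c, "mean"]),
                        float(stats.table.loc[c, "sigma"]))
                    for c in stats.table.index})


def _snapshot_hash(snapshot) -> str:
    raw = snapshot.raw if isinstance(snapshot, SolvatedSnapshot) else snapshot
    h = hashlib.sha1()
    h.update(np.ascontiguousarray(raw.solute_positions).tobytes())
    h.update(np.ascontiguousarray(raw.water_positions).tobytes())
    h.update(np.ascontiguousarray(raw.water_charges).tobytes())
    if raw.water_dipoles is not None:
        h.update(np.ascontiguousarray(raw.water_dipoles).tobytes())
    return h.hexdigest()[:16]


def run_scan(raw_snapshot, sizes, reference_size=None,
             config: EDAConfig = EDAConfig(), cache=None) -> ScanResult:
    """One decomposition per QM size; deviations against the reference.

    ``cache`` may be a dict shared between calls; entries are keyed by
    (snapshot hash, size, config hash) so repeated scans are incremental.
    Per-size failures are recorded and the scan continues.
    """
    sizes = sorted(int(s) for s in sizes)
    if reference_size is None:
        reference_size = max(sizes)
    if reference_size not in sizes:
        raise ValueError(
            f"reference_size {reference_size} not among sizes {sizes}")
    cache = {} if cache is None else cache
    snap_key = _snapshot_hash(raw_snapshot)
    cfg_key = hashlib.sha1(config.key().encode()).hexdigest()[:12]

    results = {}
    failures = {}
    for s in sizes:
        key = (snap_key, s, cfg_key)
        if key in cache:
            results[s] = cache[key]
            continue
        try:
            snap = partition_closest_n(raw_snapshot, s)
            res = assemble_eda(snap, config)
            cache[key] = res
            results[s] = res
        except Exception as exc:  # per-size failure: record, continue
            results[s] = None
            failures[s] = f"{type(exc).__name__}: {exc}"

    deviations = {}
    ref = results.get(reference_size)
    for s in sizes:
        res = results[s]
        if res is None or ref is None:
            deviations[s] = {c: float("nan") for c in COMPONENTS}
        else:
            rc, cc = ref.components(), res.components()
            deviations[s] = {c: cc[c] - rc[c] for c in COMPONENTS}
    return ScanResult(sizes=sizes, results=results,
                      reference_size=reference_size, deviations=deviations,
                      failures=failures)


def converged_size(scan: ScanResult, tolerance: float = 1.0):
    """Smallest size staying within ±tolerance for it and all larger sizes.

    Returns None when no size qualifies (the band must hold through the
    end of the scan, not merely be entered once).
    """
    if scan.missing_sizes:
        raise ValueError(
            f"scan incomplete; missing sizes {scan.missing_sizes}")
    ok = []
    for s in scan.sizes:
        dev = scan.deviations[s]
        ok.append(all(abs(dev[c]) <= tolerance for c in COMPONENTS))
    for i, s in enumerate(scan.sizes):
        if all(ok[i:]):
            return s
    return None


def sample_stats(results) -> SampleStats:
    """Per-component X̄, sample σ and RSTD = 100·σ/|X̄| over an ensemble."""
    results = list(results)
    if len(results) < 2:
        raise ValueError("need at least 2 results for sample statistics")
    hashes = {r.metadata.get("config_hash") for r in results
              if isinstance(r, EDAResult)}
    if len(hashes) > 1:
        raise ValueError(f"mixed configurations in sample: {sorted(hashes)}")
    rows = {}
    for c in COMPONENTS:
        vals = np.array([r.components()[c] for r in results])
        mean = float(vals.mean())
        sigma = float(vals.std(ddof=1))
        rstd = 100.0 * sigma / abs(mean) if mean != 0.0 else float("nan")
        rows[c] = {"mean": mean, "sigma": sigma, "rstd": rstd}
    table = pd.DataFrame(rows).T.loc[list(COMPONENTS)]
    return SampleStats(table=table, n_samples=len(results))


def sample_mean_convergence(results, step: int = 1,
                            tolerance: float = 1.0):
    """Running means over equispaced subsamples of a time-ordered ensemble.

    For k = 2, 2+step, ... n the subsample takes indices
    0, n//k, 2·(n//k), ... (index-equispaced); reported values are the
    per-component deviation of the subsample mean from the full-sample
    mean.  Returns (DataFrame indexed by k, smallest flagged k with all
    deviations within ±tolerance — or None).
    """
    results = list(results)
    n = len(results)
    if n < 2:
        raise ValueError("need at least 2 results")
    full = {c: np.mean([r.components()[c] for r in results])
            for c in COMPONENTS}
    ks = list(range(2, n, max(1, int(step)))) + [n]
    rows = {}
    for k in sorted(set(ks)):
        stride = n // k
        idx = [i * stride for i in range(k)]
        sub = [results[i] for i in idx]
        rows[k] = {c: float(np.mean([r.components()[c] for r in sub])
                            - full[c]) for c in COMPONENTS}
    frame = pd.DataFrame(rows).T
    flagged = None
    for k in frame.index:
        if all(abs(frame.loc[k, c]) <= tolerance for c in COMPONENTS):
            flagged = int(k)
            break
    return frame, flagged


def scan_to_frame(scan: ScanResult) -> pd.DataFrame:
    """Long-format table: size, component, value, deviation."""
    rows = []
    for s in scan.sizes:
        res = scan.results.get(s)
        for c in COMPONENTS:
            rows.append({
                "size": s, "component": c,
                "value": res.components()[c] if res is not None
                else float("nan"),
                "deviation": scan.deviations[s][c]})
    return pd.DataFrame(rows)


def plot_deviations(scan: ScanResult, path, tolerance=1.0):
    """Deviation-vs-QM-size curves with the ±tolerance band (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for c in COMPONENTS:
        series = scan.deviation_series(c)
        ax.plot(list(series), list(series.values()), marker="o", label=c)
    ax.axhline(tolerance, ls="--", c="k", lw=0.8)
    ax.axhline(-tolerance, ls="--", c="k", lw=0.8)
    ax.set_xlabel("QM water molecules")
    ax.set_ylabel(r"$E_i^n - E_i^{ref}$ (kcal/mol)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_normal_distributions(summary: NormalSummary, path):
    """Normal probability densities per component (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(6, 4))
    for c, (mean, sigma) in summary.parameters.items():
        if not np.isfinite(sigma) or sigma <= 0:
            continue
        x = np.linspace(mean - 4 * sigma, mean + 4 * sigma, 200)
        ax.plot(x, summary.pdf(c, x), label=c)
    ax.set_xlabel("energy (kcal/mol)")
    ax.set_ylabel("probability density")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
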