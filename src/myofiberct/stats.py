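"""Group-comparison statistics and report generation.

Wraps the comparisons run on pipeline outputs: two-sample
Kolmogorov–Smirnov on metric distributions across segments, Student's t /
Mann–Whitney U on whole-section values, comparison of transmural-profile
regression slopes (B1) between groups, and Bland–Altman agreement of paired
mass series.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats as sps

from .mass import BlandAltman, MassResult
from .metrics import MetricMap
from .regional import TransmuralProfile

__all__ = ["GroupComparison", "compare_distributions", "compare_profile_slopes", "render_report"]

_TESTS = {
    "ks": lambda a, b: sps.ks_2samp(a, b),
    "t": lambda a, b: sps.ttest_ind(a, b),
    "mannwhitney": lambda a, b: sps.mannwhitneyu(a, b),
}


@dataclass
class GroupComparison:
    """One statistical comparison between two disjoint groups."""

    metric: str
    group_a: str
    group_b: str
    test: str
    statistic: float
    pvalue: float
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "metric": self.metric,
            "group_a": self.group_a,
            "group_b": self.group_b,
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
        }
        d.update({k: v for k, v in self.extra.items() if np.isscalar(v)})
        return d


def compare_distributions(
    samples_a: np.ndarray,
    samples_b: np.ndarray,
    test: str = "ks",
    metric: str = "",
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Two-sample test on raw (unbinned) samples.

    ``test`` is ``"ks"`` (Kolmogorov–Smirnov, statistic = max CDF gap),
    ``"t"`` (Student's independent t) or ``"mannwhitney"``.
    """
    a = np.asarray(samples_a, dtype=float)
    b = np.asarray(samples_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per group")
    if test not in _TESTS:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(_TESTS)}")
    res = _TESTS[test](a, b)
    pvalue = float(res.pvalue)
    statistic = float(res.statistic)
    if test == "t" and not np.isfinite(statistic):
        # identical zero-variance groups: no difference
        statistic, pvalue = 0.0, 1.0
    return GroupComparison(
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        test=test,
        statistic=statistic,
        pvalue=pvalue,
    )


def compare_profile_slopes(
    profiles_a: Sequence[TransmuralProfile],
    profiles_b: Sequence[TransmuralProfile],
    group_a: str = "A",
    group_b: str = "B",
) -> GroupComparison:
    """Compare HA transmural-profile regression slopes (B1) between groups.

    Reports group mean (SD) of B1 and a two-sample t-test on the slopes,
    plus per-depth-bin Mann–Whitney comparisons of the binned means
    (pairwise-complete over profiles) in ``extra["per_bin"]``.
    """
    if len(profiles_a) < 2 or len(profiles_b) < 2:
        raise ValueError("need at least 2 profiles per group")
    slopes_a = np.array([p.slope for p in profiles_a], dtype=float)
    slopes_b = np.array([p.slope for p in profiles_b], dtype=float)
    if np.array_equal(slopes_a, slopes_b) and np.ptp(slopes_a) == 0:
        statistic, pvalue = 0.0, 1.0
    else:
        res = sps.ttest_ind(slopes_a, slopes_b)
        statistic, pvalue = float(res.statistic), float(res.pvalue)
        if not np.isfinite(statistic):
            statistic, pvalue = 0.0, 1.0

    centers = profiles_a[0].bin_centers
    rows = []
    for i, c in enumerate(centers):
        va = np.array([p.mean[i] for p in profiles_a])
        vb = np.array([p.mean[i] for p in profiles_b])
        va, vb = va[np.isfinite(va)], vb[np.isfinite(vb)]
        if va.size < 2 or vb.size < 2:
            rows.append({"depth": float(c), "statistic": np.nan, "pvalue": np.nan})
            continue
        if np.ptp(np.r_[va, vb]) == 0:
            rows.append({"depth": float(c), "statistic": np.nan, "pvalue": 1.0})
            continue
        r = sps.mannwhitneyu(va, vb)
        rows.append({"depth": float(c), "statistic": float(r.statistic), "pvalue": float(r.pvalue)})
    per_bin = pd.DataFrame(rows)
    return GroupComparison(
        metric="HA transmural slope B1",
        group_a=group_a,
        group_b=group_b,
        test="t-on-slopes",
        statistic=statistic,
        pvalue=pvalue,
        extra={
            "mean_a": float(slopes_a.mean()),
            "sd_a": float(slopes_a.std(ddof=1)),
            "mean_b": float(slopes_b.mean()),
            "sd_b": float(slopes_b.std(ddof=1)),
            "mean_difference": float(slopes_a.mean() - slopes_b.mean()),
            "per_bin": per_bin,
        },
    )


def _plot_map(metric: MetricMap, slice_index: int, path: str) -> None:
    vals = metric.values[slice_index]
    fig, ax = plt.subplots(figsize=(4, 4))
    if metric.name == "HA":
        im = ax.imshow(vals, cmap="twilight_shifted", vmin=-90, vmax=90)
    else:
        im = ax.imshow(vals, cmap="inferno", vmin=0, vmax=1)
    fig.colorbar(im, ax=ax, label=metric.name)
    ax.set_title(f"{metric.name}, slice {slice_index}")
    ax.axis("off")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)


def _histogram_frame(hists: dict[str, dict], metric: str) -> pd.DataFrame:
    rows = []
    for region, h in hists.items():
        if h.get("density") is None:
            continue
        edges = h["edges"]
        for lo, hi, d in zip(edges[:-1], edges[1:], h["density"]):
            rows.append(
                {"metric": metric, "region": region, "bin_low": lo, "bin_high": hi, "density": d, "n": h["n"]}
            )
    return pd.DataFrame(rows)


def render_report(results: dict, outdir: str, slice_index: int | None = None) -> dict:
    """Write a JSON + CSV + PNG report bundle from pipeline outputs.

    ``results`` may hold any of: ``seed``, ``metrics`` (name -> MetricMap),
    ``histograms`` (metric -> region histograms), ``profiles``
    (metric or group -> {segment: TransmuralProfile}), ``comparisons``
    (list of GroupComparison), ``mass`` (list of MassResult),
    ``agreement`` (BlandAltman), ``fibrosis`` (list of dict rows).
    Missing sections are recorded as explicit gaps; CSV/JSON outputs are
    byte-identical across re-runs with the same inputs.
    """
    os.makedirs(outdir, exist_ok=True)
    report: dict = {"seed": results.get("seed"), "sections": {}, "gaps": []}
    expected = ["metrics", "histograms", "profiles", "comparisons", "mass", "agreement", "fibrosis"]
    for key in expected:
        if key not in results or results[key] in (None, [], {}):
            report["gaps"].append(key)

    metrics: dict[str, MetricMap] = results.get("metrics") or {}
    for name, mm in metrics.items():
        vals = mm.valid_values()
        report["sections"].setdefault("metrics", {})[name] = {
            "n_valid": int(vals.size),
            "mean": float(vals.mean()) if vals.size else None,
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else None,
        }
        k = slice_index if slice_index is not None else mm.values.shape[0] // 2
        _plot_map(mm, k, os.path.join(outdir, f"map_{name.lower()}.png"))

    hists = results.get("histograms") or {}
    if hists:
        frames = [_histogram_frame(h, m) for m, h in hists.items()]
        df = pd.concat(frames, ignore_index=True)
        df.to_csv(os.path.join(outdir, "histograms.csv"), index=False)
        report["sections"]["histograms"] = {"metrics": sorted(hists)}
        for m, h in hists.items():
            fig, ax = plt.subplots(figsize=(5, 3))
            for region, hh in h.items():
                if hh.get("density") is None:
                    continue
                mids = 0.5 * (hh["edges"][:-1] + hh["edges"][1:])
                ax.plot(mids, hh["density"], label=region)
            ax.set_xlabel(m)
            ax.set_ylabel("density")
            ax.legend(fontsize=6)
            fig.savefig(os.path.join(outdir, f"hist_{m.lower()}.png"), dpi=100, bbox_inches="tight")
            plt.close(fig)

    profiles = results.get("profiles") or {}
    if profiles:
        rows = []
        reg_rows = []
        fig, ax = plt.subplots(figsize=(5, 3))
        for segment, prof in profiles.items():
            frame = prof.to_frame()
            rows.append(frame)
            reg_rows.append(
                {
                    "segment": segment,
                    "slope_b1": prof.slope,
                    "intercept": prof.intercept,
                    "r_squared": prof.r_squared,
                }
            )
            ax.plot(prof.bin_centers, prof.mean, marker="o", ms=2, label=segment)
        ax.set_xlabel("normalized wall depth (endo -> epi)")
        ax.set_ylabel("HA (deg)")
        ax.legend(fontsize=6)
        fig.savefig(os.path.join(outdir, "profiles.png"), dpi=100, bbox_inches="tight")
        plt.close(fig)
        pd.concat(rows, ignore_index=True).to_csv(os.path.join(outdir, "profiles.csv"), index=False)
        pd.DataFrame(reg_rows).to_csv(os.path.join(outdir, "regression.csv"), index=False)
        report["sections"]["profiles"] = {"segments": sorted(profiles)}

    comparisons = results.get("comparisons") or []
    if comparisons:
        pd.DataFrame([c.to_dict() for c in comparisons]).to_csv(
            os.path.join(outdir, "comparisons.csv"), index=False
        )
        report["sections"]["comparisons"] = [c.to_dict() for c in comparisons]

    mass: list[MassResult] = results.get("mass") or []
    if mass:
        pd.DataFrame(
            [
                {
                    "method": m.method,
                    "volume_mm3": m.volume_mm3,
                    "volume_ml": m.volume_ml,
                    "mass_g": m.mass_g,
                    "density_g_per_ml": m.density_g_per_ml,
                    "n_slices": m.n_slices,
                    "stride": m.stride,
                }
                for m in mass
            ]
        ).to_csv(os.path.join(outdir, "mass.csv"), index=False)
        report["sections"]["mass"] = {m.method: m.mass_g for m in mass}

    agreement: BlandAltman | None = results.get("agreement")
    if agreement is not None:
        report["sections"]["agreement"] = {
            "bias": agreement.bias,
            "loa_low": agreement.loa_low,
            "loa_high": agreement.loa_high,
        }
        with open(os.path.join(outdir, "agreement.json"), "w") as fh:
            json.dump(report["sections"]["agreement"], fh, indent=2, sort_keys=True)

    fibrosis = results.get("fibrosis") or []
    if fibrosis:
        pd.DataFrame(fibrosis).to_csv(os.path.join(outdir, "fibrosis.csv"), index=False)
        report["sections"]["fibrosis"] = fibrosis

    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
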