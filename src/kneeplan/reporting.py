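"""RMSD summaries, percent reductions, and export of planning reports.

Post-operative curves are compared with the pre-diseased reference by
root-mean-square deviation (RMSD) over the flexion arc, per variable.
Translations are summarized as mean +/- sample standard deviation over
{AP, LM, PD} and rotations over {EI, VV}; FE is the driven coordinate
and is excluded.  Ligament strain RMSDs are reported in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward_sim import SimulationTrace
from .objective import KINEMATIC_VARIABLES

__all__ = ["RmsdReport", "rmsd", "percent_reduction", "build_report",
           "plot_comparison"]

TRANSLATIONS = ("ap", "lm", "pd")
ROTATIONS = ("ei", "vv")


def rmsd(curve_a, curve_b) -> float:
    """Root-mean-square deviation between two equally sampled curves."""
    a = np.asarray(curve_a, float)
    b = np.asarray(curve_b, float)
    if a.shape != b.shape:
        raise ValueError(f"curve length mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(np.mean((a - b) ** 2)))


def percent_reduction(baseline: float, optimized: float) -> float:
    """Relative reduction 100*(baseline - optimized)/baseline, in percent.

    Display convention is one decimal (e.g. 2.4 -> 0.8 mm is 66.7%);
    the returned value is unrounded.
    """
    if baseline <= 0.0:
        raise ValueError("baseline must be > 0")
    return 100.0 * (baseline - optimized) / baseline


@dataclass(frozen=True)
class RmsdReport:
    """Per-variable RMSDs plus the standard summary statistics.

    ``kinematic`` maps ap/lm/pd (mm) and ei/vv (deg) to their RMSD;
    ``strain_percent`` maps ligament names to strain RMSD in percent.
    Summaries use the sample (n-1) standard deviation over 3
    translations and 2 rotations respectively.
    """

    kinematic: dict
    strain_percent: dict
    translation_mean: float
    translation_sd: float
    rotation_mean: float
    rotation_sd: float

    def summary_line(self) -> str:
        return (f"{self.translation_mean:.1f} ± {self.translation_sd:.1f} mm "
                f"(translations), {self.rotation_mean:.1f} ± "
                f"{self.rotation_sd:.1f}° (rotations)")

    def kinematic_frame(self):
        import pandas as pd
        return pd.DataFrame({"variable": list(self.kinematic),
                             "rmsd": list(self.kinematic.values())})

    def strain_frame(self):
        import pandas as pd
        return pd.DataFrame({"ligament": list(self.strain_percent),
                             "rmsd_percent": list(self.strain_percent.values())})


def build_report(pre_trace: SimulationTrace,
                 post_trace: SimulationTrace) -> RmsdReport:
    """RMSD report of a post-operative trace against the pre-diseased one.

    Strain RMSDs cover the ligaments present in both traces (the ACL is
    absent after cruciate-retaining implantation but its pre-diseased
    curve is still available upstream).
    """
    if pre_trace.t != post_trace.t or not np.allclose(
            pre_trace.flexion_deg, post_trace.flexion_deg, atol=1e-9):
        raise ValueError("traces are on different flexion grids")
    pre_k = pre_trace.kinematics_array()
    post_k = post_trace.kinematics_array()
    kinematic = {v: rmsd(pre_k[:, i], post_k[:, i])
                 for i, v in enumerate(KINEMATIC_VARIABLES)}
    shared = [n for n in pre_trace.ligament_names
              if n in post_trace.ligament_names]
    strain = {n: 100.0 * rmsd(pre_trace.strain_curve(n),
                              post_trace.strain_curve(n))
              for n in shared}
    tr = np.array([kinematic[v] for v in TRANSLATIONS])
    ro = np.array([kinematic[v] for v in ROTATIONS])
    return RmsdReport(kinematic=kinematic, strain_percent=strain,
                      translation_mean=float(tr.mean()),
                      translation_sd=float(tr.std(ddof=1)),
                      rotation_mean=float(ro.mean()),
                      rotation_sd=float(ro.std(ddof=1)))


def plot_comparison(pre_trace: SimulationTrace, traces: dict, out_path=None):
    """Overlay kinematic and strain curves (pre-diseased vs named traces).

    ``traces`` maps labels (e.g. 'MA', 'ST5') to SimulationTraces.
    Returns the matplotlib figure; saves to ``out_path`` when given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    shared = [n for n in pre_trace.ligament_names
              if all(n in t.ligament_names for t in traces.values())]
    n_rows = 2 + (len(shared) + 4) // 5
    fig, axes = plt.subplots(n_rows, 5, figsize=(16, 3 * n_rows))
    pre_k = pre_trace.kinematics_array()
    units = {"ap": "mm", "lm": "mm", "pd": "mm", "ei": "deg", "vv": "deg"}
    for i, var in enumerate(KINEMATIC_VARIABLES):
        ax = axes[0, i]
        ax.plot(pre_trace.flexion_deg, pre_k[:, i], "k-", label="pre-diseased")
        for label, t in traces.items():
            ax.plot(t.flexion_deg, t.kinematics_array()[:, i], label=label)
        ax.set_title(f"{var.upper()} ({units[var]})")
        ax.invert_xaxis()
    axes[0, 0].legend(fontsize=7)
    for j, name in enumerate(shared):
        ax = axes.flat[5 + j]
        ax.plot(pre_trace.flexion_deg, 100 * pre_trace.strain_curve(name), "k-")
        for label, t in traces.items():
            ax.plot(t.flexion_deg, 100 * t.strain_curve(name), label=label)
        ax.set_title(f"{name} strain (%)")
        ax.invert_xaxis()
    for ax in axes.flat[5 + len(shared):]:
        ax.axis("off")
    for ax in axes.flat:
        ax.tick_params(labelsize=7)
    fig.supxlabel("knee flexion (deg)")
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
    return fig
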