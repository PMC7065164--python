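"""Profile figures: subject curves over the normative band.

CSA is drawn as a continuous line, qT2 as discrete slice markers, the
normative range (mu +/- z sigma) as a shaded band, abnormal points as
highlighted markers, and tail|body and body|head transitions as vertical
dotted lines.  The x axis runs posterior to anterior (labelled P-A).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .normstats import AbnormalityReport, NormativeModel
from .profiling import Profile, RegionPartition

__all__ = ["render_profile_figure"]

_UNITS = {"csa": "CSA (mm$^2$)", "qt2": "qT2 (ms)"}


def _panel(ax, profile: Profile | None, model: NormativeModel,
           report: AbnormalityReport | None,
           partition: RegionPartition | None) -> None:
    ax.fill_between(model.grid, model.lower, model.upper,
                    color="#aaccee", alpha=0.8, label="normative range")
    ax.plot(model.grid, model.mu, "--", color="#336699", lw=1,
            label="control mean")
    if profile is not None:
        if profile.sampling == "continuous-1mm":
            ax.plot(profile.positions, profile.values, "k-", lw=1.5,
                    label="subject")
        else:
            ax.plot(profile.positions, profile.values, "kx", ms=7,
                    label="subject")
    if report is not None and report.flags.any():
        ax.plot(report.abnormal_positions, report.values[report.flags],
                "r*", ms=9, label="abnormal")
    if partition is not None:
        for x in (partition.tail_body_mm, partition.body_head_mm):
            ax.axvline(x, color="0.4", ls=":", lw=1)
    ax.set_xlabel("P-A position (mm)")
    ax.set_ylabel(_UNITS[model.modality])
    ax.set_title(f"{model.side} {model.modality.upper()}")


def render_profile_figure(
    profiles: dict[str, Profile | None],
    models: dict[str, NormativeModel],
    reports: dict[str, AbnormalityReport | None] | None = None,
    partitions: dict[str, RegionPartition] | None = None,
    path: str | Path | None = None,
    title: str = "",
):
    """One panel per (modality, side) key present in ``models``.

    Keys are ``"csa/left"``-style strings; ``profiles`` and ``reports``
    may omit keys (a missing qT2 profile renders the band alone).
    Returns the matplotlib figure; writes it to ``path`` when given.
    """
    keys = sorted(models)
    if not keys:
        raise ValueError("no models to plot")
    fig, axes = plt.subplots(1, len(keys), figsize=(6 * len(keys), 4),
                             squeeze=False)
    for ax, key in zip(axes[0], keys):
        modality, _, side = key.partition("/")
        _panel(ax, profiles.get(key), models[key],
               (reports or {}).get(key),
               (partitions or {}).get(side))
        ax.legend(loc="best", fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
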