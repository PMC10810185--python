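"""Minimal plots for the two figures practitioners actually look at."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .composition import DinucleotideProfile
from .metagene import N_BODY_BINS, N_FLANK_BINS


def plot_metagene(profile: pd.DataFrame, path: str | Path,
                  title: str = "") -> None:
    """TS/NTS unit-gene curves with TSS and TES markers."""
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.plot(profile["bin"], profile["ts"], label="TS", color="tab:red")
    ax.plot(profile["bin"], profile["nts"], label="NTS", color="tab:blue")
    for x, name in ((N_FLANK_BINS + 0.5, "TSS"),
                    (N_FLANK_BINS + N_BODY_BINS + 0.5, "TES")):
        ax.axvline(x, color="grey", lw=0.8, ls="--")
        ax.text(x, ax.get_ylim()[1], name, ha="center", va="bottom",
                fontsize=8)
    ax.set_xlabel("unit-gene bin")
    ax.set_ylabel("mean RPKM")
    ax.legend(frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_dinucleotide(profiles: dict[str, DinucleotideProfile],
                      path: str | Path) -> None:
    """Pyrimidine-pair frequency by 3'-offset, one curve per compartment."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for name, prof in profiles.items():
        ax.plot(prof.offsets_3prime, prof.pyrimidine_fraction, marker="o",
                ms=3, label=name)
    ax.invert_xaxis()  # 3' terminus on the right
    ax.set_xlabel("3'-offset of dinucleotide")
    ax.set_ylabel("pyrimidine-pair frequency")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
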