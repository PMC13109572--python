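"""Optional figure output: vertical profile curves and monthly series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import pandas as pd  # noqa: E402


def plot_vertical_profile(profile: pd.DataFrame, path) -> None:
    """Mean fPAR against height-bin midpoint (bins from vertical_profile)."""
    fig, ax = plt.subplots(figsize=(4, 5))
    mid = (profile["bin_low"] + profile["bin_high"]) / 2
    ax.plot(profile["mean"], mid, marker="o")
    ax.set_xlabel("mean fPAR")
    ax.set_ylabel("height (m)")
    ax.set_xlim(0, 1)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_monthly_series(series: pd.DataFrame, path,
                        date_column: str = "date",
                        value_column: str = "mean") -> None:
    """Stand-mean fPAR per acquisition date; gaps stay gaps (no
    interpolation across missing months)."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    data = series.sort_values(date_column)
    ax.plot(pd.to_datetime(data[date_column]), data[value_column],
            marker="o")
    ax.set_ylabel("stand mean fPAR")
    fig.autofmt_xdate()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
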