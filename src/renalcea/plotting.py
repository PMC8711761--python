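"""Optional figure helpers (tornado diagram, acceptability curves).

Thin layer over matplotlib; the analysis itself only produces tables.
Requires the ``plot`` extra.
"""

from __future__ import annotations

import pandas as pd


def plot_tornado(table: pd.DataFrame, top: int = 12, ax=None):
    """Horizontal tornado diagram from a one-way sensitivity table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 0.4 * min(top, len(table)) + 1))
    rows = table.head(top).iloc[::-1]
    base = rows["icer_base"].iloc[0]
    lo = rows[["icer_low", "icer_high"]].min(axis=1)
    hi = rows[["icer_low", "icer_high"]].max(axis=1)
    ax.barh(rows["parameter"], hi - lo, left=lo, color="#4878d0")
    ax.axvline(base, color="k", lw=1)
    ax.set_xlabel("ICER (USD/QALY)")
    return ax


def plot_ceac(curve: pd.DataFrame, wtp_mark: float | None = 150_000.0, ax=None):
    """Cost-effectiveness acceptability curves for both strategies."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve["wtp"], curve["p_intervention"], label="nivolumab + cabozantinib")
    ax.plot(curve["wtp"], curve["p_comparator"], label="sunitinib")
    if wtp_mark is not None:
        ax.axvline(wtp_mark, color="k", ls="--", lw=1)
    ax.set_xlabel("Willingness to pay (USD/QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend()
    return ax
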