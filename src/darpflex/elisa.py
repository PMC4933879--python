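"""ELISA-based affinity ranking of binder variants.

Variants are ranked by the ratio of their ELISA signal to a reference
(parent) binder, measured after incubation with free competitor ligand so
that rebinding of dissociated binder is suppressed (an off-rate ranking).
The ratio bands are: low < 2x, medium 3-6x, high >= 8x the reference.
Ratios falling in the gaps (2-3, 6-8) are reported as indeterminate rather
than forced into a neighboring class, because the bands do not tile the
ratio axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ElisaPanel", "classify_affinity", "rank_panel"]

CATEGORIES = ("low", "medium", "high", "indeterminate")


class ElisaError(ValueError):
    pass


@dataclass
class ElisaPanel:
    """Per-variant ELISA signals under buffer and competitor conditions.

    ``data`` has columns: variant, condition ("buffer" | "competitor"),
    replicate (int), signal (absorbance, a.u., >= 0).
    """

    data: pd.DataFrame
    reference: str
    true_categories: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    def __post_init__(self) -> None:
        required = {"variant", "condition", "replicate", "signal"}
        missing = required - set(self.data.columns)
        if missing:
            raise ElisaError(f"panel missing columns {sorted(missing)}")
        if (self.data["signal"] < 0).any():
            raise ElisaError("negative ELISA signals")
        if self.reference not in set(self.data["variant"]):
            raise ElisaError(f"reference variant {self.reference!r} not in panel")


def classify_affinity(ratio: float) -> str:
    """Affinity class of a competitor-condition signal ratio vs reference.

    low iff ratio < 2; medium iff 3 <= ratio <= 6; high iff ratio >= 8;
    gap ranges [2, 3) and (6, 8) are "indeterminate".
    """
    if not np.isfinite(ratio) or ratio < 0:
        raise ElisaError(f"ratio must be >= 0 and finite, got {ratio!r}")
    if ratio < 2:
        return "low"
    if 3 <= ratio <= 6:
        return "medium"
    if ratio >= 8:
        return "high"
    return "indeterminate"


def rank_panel(panel: ElisaPanel) -> pd.DataFrame:
    """Rank every variant in the panel against the reference.

    Ratios use replicate-mean competitor-condition signals; buffer-condition
    ratios are reported as an auxiliary column.  Returns a DataFrame indexed
    by variant with columns: ratio, ratio_buffer, signal_mean, signal_sd,
    category.
    """
    comp = panel.data[panel.data["condition"] == "competitor"]
    if comp.empty:
        raise ElisaError("panel has no competitor-condition signals")
    buf = panel.data[panel.data["condition"] == "buffer"]

    stats = comp.groupby("variant")["signal"].agg(["mean", "std", "count"])
    ref_signal = stats.loc[panel.reference, "mean"]
    if ref_signal == 0:
        raise ElisaError("reference competitor-condition signal is zero")
    buf_mean = buf.groupby("variant")["signal"].mean() if not buf.empty else None

    rows = []
    for variant, row in stats.iterrows():
        ratio = row["mean"] / ref_signal
        ratio_buffer = np.nan
        if buf_mean is not None and variant in buf_mean.index:
            ref_buf = buf_mean.get(panel.reference, np.nan)
            if ref_buf and np.isfinite(ref_buf):
                ratio_buffer = buf_mean[variant] / ref_buf
        rows.append(
            {
                "variant": variant,
                "ratio": ratio,
                "ratio_buffer": ratio_buffer,
                "signal_mean": row["mean"],
                "signal_sd": 0.0 if row["count"] < 2 else row["std"],
                "category": classify_affinity(ratio),
            }
        )
    out = pd.DataFrame(rows).set_index("variant")
    return out.sort_values("ratio", ascending=False)
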