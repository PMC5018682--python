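"""Relative expression from qPCR threshold cycles (the delta-CT method).

For each biological replicate, technical-run CT values are averaged
arithmetically on the cycle scale, delta-CT = CT_target - CT_reference, and
the relative level is 2**(-delta-CT) (fold over the reference gene; no
calibrator sample). Biological replicates are summarized by the geometric
mean on the ratio scale. A missing/empty CT (no amplification) yields level
0 with a below-detection flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import FormatError

_COLUMNS = ["sample", "gene", "replicate", "run", "ct"]


@dataclass
class CtTable:
    """Long-format CT table: one row per (sample, gene, replicate, run).

    ``ct`` is the threshold cycle; NaN encodes the no-amplification sentinel.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise FormatError(f"CT table missing column(s): {missing}")
        self.data = self.data[_COLUMNS].copy()
        ct = self.data["ct"]
        if ((ct <= 0) & ct.notna()).any():
            raise FormatError("CT values must be positive (or empty for no amplification)")

    @classmethod
    def read_csv(cls, path: str | Path) -> "CtTable":
        return cls(pd.read_csv(path))

    def write_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)


@dataclass
class ExpressionResult:
    target: str
    reference: str
    per_replicate: dict                 # (sample, replicate) -> level
    below_detection: list               # (sample, replicate) keys with no amplification
    summary: float                      # geometric mean over detected replicates (0 if none)


def relative_expression(table: CtTable, target: str, reference: str) -> ExpressionResult:
    """Per-replicate and summary relative expression of target vs reference."""
    df = table.data
    genes = set(df["gene"])
    for g in (target, reference):
        if g not in genes:
            raise FormatError(f"gene {g!r} absent from the CT table")

    mean_ct = (df.groupby(["sample", "gene", "replicate"])["ct"]
                 .apply(lambda s: float(np.mean(s)) if s.notna().all() and len(s) else float("nan")))
    levels: dict = {}
    below: list = []
    keys = sorted({(s, r) for s, g, r in mean_ct.index if g == target})
    for sample, rep in keys:
        if (sample, reference, rep) not in mean_ct.index:
            raise FormatError(f"replicate ({sample!r}, {rep!r}) lacks the reference gene {reference!r}")
        ct_t = mean_ct[(sample, target, rep)]
        ct_r = mean_ct[(sample, reference, rep)]
        if np.isnan(ct_r):
            raise FormatError(f"reference gene did not amplify for ({sample!r}, {rep!r})")
        if np.isnan(ct_t):
            levels[(sample, rep)] = 0.0
            below.append((sample, rep))
        else:
            levels[(sample, rep)] = float(2.0 ** (-(ct_t - ct_r)))
    detected = [v for k, v in levels.items() if k not in set(below)]
    if detected:
        summary = float(np.exp(np.mean(np.log(detected))))
    else:
        summary = 0.0
    return ExpressionResult(target=target, reference=reference,
                            per_replicate=levels, below_detection=below,
                            summary=summary)


def expression_table(table: CtTable, targets: Sequence[str], reference: str) -> pd.DataFrame:
    """Tidy per-target summary (one row per target gene)."""
    rows = []
    for t in targets:
        res = relative_expression(table, t, reference)
        rows.append({"target": t, "reference": reference,
                     "summary_level": res.summary,
                     "n_replicates": len(res.per_replicate),
                     "n_below_detection": len(res.below_detection)})
    return pd.DataFrame(rows)
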