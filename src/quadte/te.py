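"""Translational efficiency (TE) from polysome-profiling FPKM tables.

TE = FPKM-polysome / FPKM-total, per condition.  The KO/Ctrl fold change
dTE = TE_KO / TE_Ctrl (log2 reported) is computed per replicate for the
consistency filter and on replicate-averaged FPKMs for categorization:

* a gene is *consistent* when both replicates move the same direction;
* te/mrna categories: up when the fold change >= 1.5, down when <= 0.66,
  unchanged otherwise (both bounds inclusive);
* the *expressed* filter keeps genes with averaged FPKM-total > 1 in
  either condition;
* the *stringent* TE-down set additionally requires log2(dTE) < -1 with
  constant mRNA (|log2 dFPKM-total| <= 0.585).

Input tables carry one row per gene with columns
``{total,polysome}_{ctrl,ko}_{rep1,rep2}`` (any consistent replicate
suffixes); genes with a zero denominator anywhere are flagged and excluded
from ratio-based analyses.  No pseudocounts are added.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

UP_FOLD = 1.5
DOWN_FOLD = 0.66
STRINGENT_LOG2_TE = -1.0
CONSTANT_MRNA_LOG2 = 0.585


def _required_columns(replicates: Sequence[str]) -> list[str]:
    return [
        f"{frac}_{cond}_{rep}"
        for frac in ("total", "polysome")
        for cond in ("ctrl", "ko")
        for rep in replicates
    ]


def compute_te(table: pd.DataFrame, replicates: Sequence[str] = ("rep1", "rep2")) -> pd.DataFrame:
    """Per-replicate and averaged TE values; flags zero-denominator genes.

    Returns a DataFrame indexed by ``gene_id`` with per-replicate TEs,
    averaged FPKMs, ``te_ctrl``/``te_ko`` (from averaged FPKMs), ``delta_te``
    (KO/Ctrl), ``log2_delta_te``, ``log2_delta_mrna`` and a ``defined``
    flag (False where any denominator was zero).
    """
    missing = [c for c in _required_columns(replicates) + ["gene_id"] if c not in table.columns]
    if missing:
        raise KeyError(f"expression table missing columns: {missing}")
    df = table.set_index("gene_id").copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        for rep in replicates:
            for cond in ("ctrl", "ko"):
                df[f"te_{cond}_{rep}"] = df[f"polysome_{cond}_{rep}"] / df[f"total_{cond}_{rep}"]
            df[f"delta_te_{rep}"] = df[f"te_ko_{rep}"] / df[f"te_ctrl_{rep}"]
        for frac in ("total", "polysome"):
            for cond in ("ctrl", "ko"):
                df[f"{frac}_{cond}_avg"] = df[[f"{frac}_{cond}_{r}" for r in replicates]].mean(axis=1)
        df["te_ctrl"] = df["polysome_ctrl_avg"] / df["total_ctrl_avg"]
        df["te_ko"] = df["polysome_ko_avg"] / df["total_ko_avg"]
        df["delta_te"] = df["te_ko"] / df["te_ctrl"]
        df["log2_delta_te"] = np.log2(df["delta_te"])
        df["delta_mrna"] = df["total_ko_avg"] / df["total_ctrl_avg"]
        df["log2_delta_mrna"] = np.log2(df["delta_mrna"])
    denom_cols = ([f"total_{c}_{r}" for c in ("ctrl", "ko") for r in replicates]
                  + [f"polysome_ctrl_{r}" for r in replicates]
                  + ["total_ctrl_avg", "total_ko_avg", "polysome_ctrl_avg"])
    df["defined"] = (df[denom_cols] > 0).all(axis=1)
    df["n_excluded_zero_denominator"] = (~df["defined"]).sum()
    return df


def consistency_filter(df: pd.DataFrame, replicates: Sequence[str] = ("rep1", "rep2")) -> pd.DataFrame:
    """Set ``consistent_trend``: TE moved the same (nonzero) direction in both replicates."""
    df = df.copy()
    if len(replicates) < 2:
        warnings.warn("single replicate: consistency filter bypassed")
        df["consistent_trend"] = df["defined"]
        return df
    with np.errstate(divide="ignore", invalid="ignore"):
        signs = np.sign(np.log2(df[[f"delta_te_{r}" for r in replicates]]))
    df["consistent_trend"] = df["defined"] & (signs.nunique(axis=1) == 1) & (signs != 0).all(axis=1)
    return df


def categorize(df: pd.DataFrame, up: float = UP_FOLD, down: float = DOWN_FOLD,
               expressed_min_fpkm: float = 1.0) -> pd.DataFrame:
    """TE and mRNA fold-change categories plus the expressed filter.

    Categories are assigned to consistent genes only; ``expressed`` is
    averaged FPKM-total > ``expressed_min_fpkm`` in either condition.
    """
    df = df.copy()

    def _cat(fold: pd.Series) -> pd.Series:
        out = pd.Series("unchanged", index=fold.index)
        out[fold >= up] = "up"
        out[fold <= down] = "down"
        return out

    usable = df["consistent_trend"]
    df["te_category"] = pd.NA
    df.loc[usable, "te_category"] = _cat(df.loc[usable, "delta_te"])
    df["mrna_category"] = pd.NA
    df.loc[usable, "mrna_category"] = _cat(df.loc[usable, "delta_mrna"])
    df["expressed"] = (df["total_ctrl_avg"] > expressed_min_fpkm) | (df["total_ko_avg"] > expressed_min_fpkm)
    return df


def stringent_te_down(df: pd.DataFrame,
                      log2_te_cut: float = STRINGENT_LOG2_TE,
                      constant_mrna_cut: float = CONSTANT_MRNA_LOG2) -> pd.Index:
    """Gene ids passing the stringent TE-down filter.

    Strictly log2(dTE) < -1 with constant mRNA (|log2 dFPKM-total| <= 0.585).
    """
    mask = (
        df["consistent_trend"].fillna(False)
        & (df["log2_delta_te"] < log2_te_cut)
        & (df["log2_delta_mrna"].abs() <= constant_mrna_cut)
    )
    return df.index[mask]
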