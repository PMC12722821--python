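"""Regulon-based transcription-factor activity scoring.

A TF is called *activated* when significantly more of its targets change
consistently with its regulation modes than expected by chance: an
Activation-mode target going up, or a Repression-mode target going down
(|log2FC| > 0.6 at FDR < 0.05).  The mirrored criterion gives the
*repressed* verdict.  Each (TF, direction) pair gets a one-sided Fisher
exact test of consistent-significant targets against the non-target
background, with BH correction across all pairs tested in the call.

Unknown-mode targets count toward the target total but can never be
consistent.  The background success criterion for a non-target gene is
"significantly changed in either direction", since consistency for targets
is mode-dependent; the alternative backgrounds are configurable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .diffexp import (
    DEFAULT_FDR_THRESHOLD,
    DEFAULT_LFC_THRESHOLD,
    benjamini_hochberg,
    classify_direction,
)
from .direction_enrichment import ContingencyTable, fisher_odds_ratio
from .errors import DataError
from .io_formats import RegulonTable


def classify_deg_direction(
    de: pd.DataFrame,
    lfc_threshold: float = DEFAULT_LFC_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.Series:
    """Strict-threshold up/down/ns labels per gene (no base-mean gate)."""
    return classify_direction(de, lfc_threshold, fdr_threshold)


def _consistent(mode: str, label: str, verdict: str) -> bool:
    if verdict == "activated":
        return (mode == "Activation" and label == "up") or (
            mode == "Repression" and label == "down"
        )
    return (mode == "Activation" and label == "down") or (
        mode == "Repression" and label == "up"
    )


def score_tf_activity(
    labels: pd.Series,
    regulons: RegulonTable,
    min_targets: int = 3,
) -> pd.DataFrame:
    """Fisher enrichment of direction-consistent targets per (TF, verdict).

    ``labels`` maps every tested gene to up/down/ns; genes absent from it
    are outside the universe and ignored.  TFs with fewer than
    ``min_targets`` tested targets are skipped (reported with NaN
    statistics in the returned table so the skip is visible).
    """
    if labels.empty:
        raise DataError("empty universe")
    universe = set(labels.index)
    sig_any = set(labels.index[labels.isin(["up", "down"])])

    rows = []
    for tf in regulons.tfs:
        reg = regulons.targets_of(tf)
        tested = reg[reg["target"].isin(universe)]
        n_tested = len(tested)
        target_set = set(tested["target"])
        bg = universe - target_set
        bg_sig = len(sig_any & bg)
        for verdict in ("activated", "repressed"):
            if n_tested < min_targets:
                rows.append({
                    "tf": tf, "direction": verdict,
                    "n_consistent": np.nan, "n_targets_tested": n_tested,
                    "bg_significant": np.nan, "bg_total": len(bg),
                    "odds_ratio": np.nan, "p": np.nan, "skipped": True,
                })
                continue
            k = sum(
                _consistent(mode, labels.get(target, "ns"), verdict)
                for target, mode in zip(tested["target"], tested["mode"])
            )
            tab = ContingencyTable(
                k, n_tested - k, bg_sig, len(bg) - bg_sig,
                label=f"{tf}:{verdict}",
            )
            res = fisher_odds_ratio(tab)
            p = 1.0 if k == 0 else res.p
            rows.append({
                "tf": tf, "direction": verdict,
                "n_consistent": k, "n_targets_tested": n_tested,
                "bg_significant": bg_sig, "bg_total": len(bg),
                "odds_ratio": res.odds_ratio, "p": p, "skipped": False,
            })

    out = pd.DataFrame(rows)
    tested_mask = ~out["skipped"]
    padj = np.full(len(out), np.nan)
    padj[tested_mask.to_numpy()] = benjamini_hochberg(
        out.loc[tested_mask, "p"].to_numpy()
    )
    out["padj"] = padj
    out["verdict"] = np.where(
        tested_mask & (out["padj"] < DEFAULT_FDR_THRESHOLD),
        "significant", "ns",
    )
    return out


def summarize_tf_groups(results: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Significant TFs split into activated and repressed tables.

    Ordering is deterministic: ascending padj, then TF id.
    """
    out = {}
    for verdict in ("activated", "repressed"):
        sub = results[
            (results["direction"] == verdict)
            & (results["verdict"] == "significant")
        ]
        out[verdict] = sub.sort_values(
            ["padj", "tf"], kind="stable"
        ).reset_index(drop=True)
    return out
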