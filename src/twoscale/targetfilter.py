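"""Consensus voting and logic filtering of miRNA target predictions.

Candidate miRNA-target interactions are accepted when predicted by at least
``min_tools`` of the available prediction tools (consensus voting), then
filtered against a developmental gene ON/OFF state table: a miRNA is kept
only if, at every stage, its predicted targets include at least ``min_off``
genes that are OFF and no gene that is ON (a functional miRNA would silence
its targets, so genes still ON cannot be among them).  Survivors are ranked
by their mean min-max-normalised per-tool prediction score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "read_prediction_table",
    "read_state_table",
    "consensus_targets",
    "logic_filter",
    "rank_candidates",
]

PREDICTION_COLUMNS = ("mirna", "gene", "tool", "score")
STATE_COLUMNS = ("gene", "stage", "state")


def read_prediction_table(path) -> pd.DataFrame:
    """Read a delimited prediction table (mirna, gene, tool, score)."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = set(PREDICTION_COLUMNS[:3]) - set(df.columns)
    if missing:
        raise ValueError(f"prediction table lacks columns {sorted(missing)}")
    if "score" not in df.columns:
        df["score"] = np.nan
    return df[list(PREDICTION_COLUMNS)]


def read_state_table(path) -> pd.DataFrame:
    """Read a delimited state table (gene, stage, state in {ON, OFF})."""
    df = pd.read_csv(path, sep=None, engine="python")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = set(STATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"state table lacks columns {sorted(missing)}")
    df["state"] = df["state"].str.upper()
    return df[list(STATE_COLUMNS)]


def _validate_predictions(pt: pd.DataFrame) -> pd.DataFrame:
    pt = pd.DataFrame(pt, columns=list(PREDICTION_COLUMNS)).copy()
    dup = pt.duplicated(subset=["mirna", "gene", "tool"])
    if dup.any():
        first = pt.loc[dup.idxmax(), ["mirna", "gene", "tool"]].tolist()
        raise ValueError(f"duplicate prediction record {first}")
    return pt


def consensus_targets(pt: pd.DataFrame, min_tools: int = 3) -> set[tuple[str, str]]:
    """(miRNA, gene) pairs predicted by at least ``min_tools`` distinct tools."""
    if min_tools < 1:
        raise ValueError("min_tools must be >= 1")
    pt = _validate_predictions(pt)
    counts = pt.groupby(["mirna", "gene"])["tool"].nunique()
    return set(counts[counts >= min_tools].index)


def logic_filter(
    candidates: set[tuple[str, str]],
    st: pd.DataFrame,
    min_off: int = 2,
) -> set[str]:
    """miRNAs whose targets are consistent with the ON/OFF table at all stages.

    A miRNA passes iff for every developmental stage its candidate target
    genes include at least ``min_off`` OFF genes and no ON gene.  Every
    candidate gene must appear in the state table.
    """
    st = pd.DataFrame(st, columns=list(STATE_COLUMNS))
    bad = st.duplicated(subset=["gene", "stage"])
    if bad.any():
        raise ValueError("state table assigns multiple states to one (gene, stage)")
    known_genes = set(st["gene"])
    for _, gene in candidates:
        if gene not in known_genes:
            raise ValueError(f"gene {gene!r} missing from the state table")
    stages = list(dict.fromkeys(st["stage"]))
    state_of = {(g, s): v for g, s, v in st.itertuples(index=False)}

    targets: dict[str, set[str]] = {}
    for mirna, gene in candidates:
        targets.setdefault(mirna, set()).add(gene)

    kept = set()
    for mirna, genes in targets.items():
        ok = True
        for stage in stages:
            states = [state_of[(g, stage)] for g in genes]
            if any(s == "ON" for s in states) or sum(s == "OFF" for s in states) < min_off:
                ok = False
                break
        if ok:
            kept.add(mirna)
    return kept


def rank_candidates(filtered: set[str], pt: pd.DataFrame) -> list[str]:
    """Rank filtered miRNAs by mean min-max-normalised per-tool score.

    Scores are normalised to [0, 1] within each tool (min-max over all
    records of that tool); each miRNA is scored by the mean of the
    normalised scores of its records (missing scores ignored).  Ties break
    lexicographically by miRNA id, so the ranking is deterministic.
    """
    if not filtered:
        return []
    pt = _validate_predictions(pt)
    known = set(pt["mirna"])
    unknown = filtered - known
    if unknown:
        raise ValueError(f"miRNAs absent from the prediction table: {sorted(unknown)}")

    pt = pt.copy()
    pt["norm"] = np.nan
    for _tool, idx in pt.groupby("tool").groups.items():
        s = pt.loc[idx, "score"].astype(float)
        lo, hi = s.min(), s.max()
        if np.isfinite(lo) and np.isfinite(hi):
            pt.loc[idx, "norm"] = 0.5 if hi == lo else (s - lo) / (hi - lo)
    agg = pt[pt["mirna"].isin(filtered)].groupby("mirna")["norm"].mean()
    agg = agg.fillna(0.0)
    return sorted(agg.index, key=lambda m: (-agg[m], m))
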