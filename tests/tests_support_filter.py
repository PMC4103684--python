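"""Shared brute-force oracles and random-instance generator for filter tests."""

import itertools

import pandas as pd

TOOLS = ["TargetScan", "PicTar", "miRNAMAP", "TargetSpy", "DIANA"]


def random_instance(rng, n_mirnas=8, n_genes=6, n_stages=3):
    mirnas = [f"miR-{i}" for i in range(n_mirnas)]
    genes = [f"g{j}" for j in range(n_genes)]
    stages = [f"E{k}" for k in range(n_stages)]
    records = [
        (m, g, t, rng.random())
        for m, g, t in itertools.product(mirnas, genes, TOOLS)
        if rng.random() < 0.35
    ]
    pt = pd.DataFrame(records, columns=["mirna", "gene", "tool", "score"])
    st = pd.DataFrame(
        [(g, s, "ON" if rng.random() < 0.4 else "OFF") for g in genes for s in stages],
        columns=["gene", "stage", "state"],
    )
    return pt, st


def brute_consensus(pt, min_tools):
    out = set()
    for (m, g), grp in pt.groupby(["mirna", "gene"]):
        if len(set(grp["tool"])) >= min_tools:
            out.add((m, g))
    return out


def brute_logic(candidates, st, min_off):
    states = {(r.gene, r.stage): r.state for r in st.itertuples()}
    stages = sorted(set(st["stage"]))
    kept = set()
    for m in {m for m, _ in candidates}:
        genes = [g for mm, g in candidates if mm == m]
        ok = True
        for s in stages:
            on = sum(states[(g, s)] == "ON" for g in genes)
            off = sum(states[(g, s)] == "OFF" for g in genes)
            if on > 0 or off < min_off:
                ok = False
        if ok:
            kept.add(m)
    return kept
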