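import itertools

import numpy as np
import pandas as pd
import pytest

from twoscale.targetfilter import consensus_targets, logic_filter, rank_candidates

TOOLS = ["TargetScan", "PicTar", "miRNAMAP", "TargetSpy", "DIANA"]


def make_predictions(records):
    return pd.DataFrame(records, columns=["mirna", "gene", "tool", "score"])


def make_states(records):
    return pd.DataFrame(records, columns=["gene", "stage", "state"])


def random_instance(rng, n_mirnas=8, n_genes=6, n_stages=3):
    mirnas = [f"miR-{i}" for i in range(n_mirnas)]
    genes = [f"g{j}" for j in range(n_genes)]
    stages = [f"E{k}" for k in range(n_stages)]
    records = []
    for m, g, t in itertools.product(mirnas, genes, TOOLS):
        if rng.random() < 0.35:
            records.append((m, g, t, rng.random()))
    pt = make_predictions(records)
    st = make_states(
        [(g, s, "ON" if rng.random() < 0.4 else "OFF") for g in genes for s in stages]
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
    mirnas = {m for m, _ in candidates}
    kept = set()
    for m in mirnas:
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


class TestConsensus:
    def test_three_of_five_included(self):
        pt = make_predictions(
            [("miR-a", "Wnt1", t, 1.0) for t in TOOLS[:3]]
            + [("miR-b", "Wnt1", t, 1.0) for t in TOOLS[:2]]
        )
        assert consensus_targets(pt, 3) == {("miR-a", "Wnt1")}

    def test_duplicate_record_rejected(self):
        pt = make_predictions(
            [("m", "g", "TargetScan", 0.5), ("m", "g", "TargetScan", 0.7)]
        )
        with pytest.raises(ValueError, match="duplicate"):
            consensus_targets(pt, 3)

    def test_monotone_in_min_tools(self):
        rng = np.random.default_rng(7)
        pt, _ = random_instance(rng)
        prev = consensus_targets(pt, 1)
        for k in range(2, 6):
            cur = consensus_targets(pt, k)
            assert cur <= prev
            prev = cur

    def test_matches_brute_force_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            pt, _ = random_instance(rng)
            for k in (1, 3, 5):
                assert consensus_targets(pt, k) == brute_consensus(pt, k)


class TestLogicFilter:
    def setup_method(self):
        self.st = make_states(
            [(g, s, st) for g, st in
             [("g1", "OFF"), ("g2", "OFF"), ("g3", "ON")]
             for s in ("E8.5", "E10.5", "E12.5")]
        )

    def test_on_gene_excludes(self):
        cand = {("m1", "g1"), ("m1", "g2"), ("m1", "g3")}
        assert logic_filter(cand, self.st) == set()

    def test_two_off_genes_included(self):
        cand = {("m1", "g1"), ("m1", "g2")}
        assert logic_filter(cand, self.st) == {"m1"}

    def test_single_off_gene_insufficient(self):
        cand = {("m1", "g1")}
        assert logic_filter(cand, self.st, min_off=2) == set()

    def test_missing_gene_error_names_gene(self):
        with pytest.raises(ValueError, match="gX"):
            logic_filter({("m1", "gX")}, self.st)

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        pt, st = random_instance(rng)
        cand = consensus_targets(pt, 2)
        shuffled = st.sample(frac=1.0, random_state=0)
        assert logic_filter(cand, st) == logic_filter(cand, shuffled)


class TestRanking:
    def test_single_candidate_first(self):
        pt = make_predictions([("m1", "g1", "TargetScan", 0.1)])
        assert rank_candidates({"m1"}, pt) == ["m1"]

    def test_dominant_candidate_ranks_first(self):
        records = []
        for t in TOOLS:
            records.append(("hi", "g1", t, 0.9))
            records.append(("lo", "g1", t, 0.1))
        pt = make_predictions(records)
        assert rank_candidates({"hi", "lo"}, pt) == ["hi", "lo"]

    def test_empty_set(self):
        pt = make_predictions([("m", "g", "TargetScan", 0.5)])
        assert rank_candidates(set(), pt) == []

    def test_matches_brute_force_aggregate(self):
        rng = np.random.default_rng(19)
        pt, _ = random_instance(rng, n_mirnas=5)
        mirnas = set(pt["mirna"])
        got = rank_candidates(mirnas, pt)
        # brute-force aggregate: per-tool min-max normalisation then mean
        norm = {}
        for t, grp in pt.groupby("tool"):
            lo, hi = grp["score"].min(), grp["score"].max()
            for r in grp.itertuples():
                norm.setdefault(r.mirna, []).append(
                    0.5 if hi == lo else (r.score - lo) / (hi - lo)
                )
        agg = {m: np.mean(v) for m, v in norm.items()}
        expected = sorted(mirnas, key=lambda m: (-agg.get(m, 0.0), m))
        assert got == expected


class TestEndToEnd:
    def test_workflow_shape_on_toy_network(self):
        """Six-gene network, Wnt1-downstream genes OFF: survivors target >= 2
        OFF genes per stage and never an ON gene."""
        rng = np.random.default_rng(23)
        genes = ["Otx2", "Gbx2", "Fgf8", "Wnt1", "En", "Pax"]
        downstream_off = {"En", "Pax", "Fgf8"}
        st = make_states(
            [
                (g, s, "OFF" if g in downstream_off else "ON")
                for g in genes
                for s in ("E8.5", "E10.5", "E12.5")
            ]
        )
        records = []
        for i in range(10):
            m = f"miR-{700 + i}"
            targets = rng.choice(genes, size=rng.integers(1, 5), replace=False)
            for g in targets:
                for t in rng.choice(TOOLS, size=rng.integers(1, 6), replace=False):
                    records.append((m, g, t, rng.random()))
        pt = make_predictions(records)
        cand = consensus_targets(pt, 3)
        kept = logic_filter(cand, st)
        assert kept == brute_logic(cand, st, 2)
        for m in kept:
            targets = {g for mm, g in cand if mm == m}
            assert len(targets & downstream_off) >= 2
            assert not targets - downstream_off


class TestBundledFixture:
    def test_toy_workflow_four_pass_two_selected(self):
        """Bundled synthetic fixture: 4 miRNAs survive the filter, miR-709
        and miR-705 rank first by aggregated prediction score."""
        from pathlib import Path

        root = Path(__file__).resolve().parents[1] / "examples"
        pt = pd.read_csv(root / "toy_predictions.csv")
        st = pd.read_csv(root / "toy_states.csv")
        kept = logic_filter(consensus_targets(pt, 3), st)
        assert len(kept) == 4
        ranked = rank_candidates(kept, pt)
        assert ranked[:2] == ["miR-709", "miR-705"]
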