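"""Abundance normalization, enrichment ratios and hit-calling rules."""

import numpy as np
import pandas as pd
import pytest

from metscreen.screen import (
    ScreenDesign,
    aggregate_replicates,
    call_met_hits,
    call_sq_hits,
    classify_hits,
    enrichment_table,
    pool_input_profile,
    relative_abundance,
)


def toy_design(n_mice=3, mets_per_mouse=2):
    pools = {"p1": {"A", "B", "C"}}
    mice = {f"m{i}": "p1" for i in range(1, n_mice + 1)}
    rows = []
    for r in (1, 2):
        rows.append({"sample_id": f"inp{r}", "pool_id": "p1", "mouse_id": np.nan,
                     "tissue": "input", "replicate": r})
    for m in mice:
        for c in (1, 2, 3):
            rows.append({"sample_id": f"{m}_sq{c}", "pool_id": "p1", "mouse_id": m,
                         "tissue": "sq_tumor", "replicate": c})
        for l in range(1, mets_per_mouse + 1):
            rows.append({"sample_id": f"{m}_met{l}", "pool_id": "p1", "mouse_id": m,
                         "tissue": "lung_met", "replicate": l})
    return ScreenDesign(pools=pools, mice=mice, samples=pd.DataFrame(rows))


def abundance_frame(design, values):
    """values: dict sample_id -> (a, b, c) abundances."""
    return pd.DataFrame(values, index=["A", "B", "C"]).T


class TestAbundance:
    def test_simple_ratio(self):
        counts = pd.DataFrame({"A": [10], "B": [30], "C": [60]}, index=["s1"])
        abund, failed = relative_abundance(counts)
        assert failed == []
        assert abund.loc["s1"].tolist() == [0.1, 0.3, 0.6]

    def test_rows_sum_to_one_and_scaling_invariance(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 1000, size=(10, 8)),
            index=[f"s{i}" for i in range(10)],
        )
        abund, _ = relative_abundance(counts)
        assert np.allclose(abund.sum(axis=1), 1.0, atol=1e-12)
        scaled, _ = relative_abundance(counts * 17)
        pd.testing.assert_frame_equal(abund, scaled)

    def test_zero_read_sample_flagged_failed(self):
        counts = pd.DataFrame({"A": [5, 0], "B": [5, 0]}, index=["ok", "dead"])
        with pytest.warns(UserWarning, match="zero assigned"):
            abund, failed = relative_abundance(counts)
        assert failed == ["dead"]
        assert list(abund.index) == ["ok"]

    def test_replicate_aggregation_closed_form(self):
        abund = pd.DataFrame({"A": [0.2, 0.4], "B": [0.8, 0.6]}, index=["r1", "r2"])
        mean, sd, n = aggregate_replicates(abund, {"r1": "g", "r2": "g"})
        assert mean.loc["g", "A"] == pytest.approx(0.3)
        assert sd.loc["g", "A"] == pytest.approx(np.sqrt(((0.2 - 0.3) ** 2 + (0.4 - 0.3) ** 2)))
        assert n["g"] == 2

    def test_single_replicate_sd_unavailable(self):
        abund = pd.DataFrame({"A": [0.5]}, index=["r1"])
        _, sd, _ = aggregate_replicates(abund, {"r1": "g"})
        assert np.isnan(sd.loc["g", "A"])


class TestEnrichment:
    def test_ratio_identity_and_dropout(self):
        design = toy_design(n_mice=1, mets_per_mouse=1)
        abund = abundance_frame(design, {
            "inp1": [0.005, 0.995, 0.0],
            "inp2": [0.005, 0.995, 0.0],
            "m1_sq1": [0.5, 0.5, 0.0],
            "m1_sq2": [0.005, 0.995, 0.0],
            "m1_sq3": [0.005, 0.995, 0.0],
            "m1_met1": [0.0, 1.0, 0.0],
        })
        enr = enrichment_table(abund, design)
        e = enr.set_index(["sample_id", "orf_id"])
        assert e.loc[("m1_sq1", "A"), "enrichment"] == pytest.approx(100.0)
        assert e.loc[("m1_sq2", "B"), "enrichment"] == pytest.approx(1.0)
        # zero input: dropout flag, no numeric ratio
        assert e.loc[("m1_met1", "C"), "dropout"]
        assert np.isnan(e.loc[("m1_met1", "C"), "enrichment"])

    def test_input_is_replicate_mean(self):
        design = toy_design(n_mice=1, mets_per_mouse=1)
        abund = abundance_frame(design, {
            "inp1": [0.02, 0.98, 0.0],
            "inp2": [0.04, 0.96, 0.0],
            "m1_sq1": [0.3, 0.7, 0.0],
            "m1_sq2": [0.3, 0.7, 0.0],
            "m1_sq3": [0.3, 0.7, 0.0],
            "m1_met1": [0.3, 0.7, 0.0],
        })
        mean, _ = pool_input_profile(abund, design)
        assert mean.loc["p1", "A"] == pytest.approx(0.03)
        enr = enrichment_table(abund, design).set_index(["sample_id", "orf_id"])
        assert enr.loc[("m1_sq1", "A"), "enrichment"] == pytest.approx(10.0)


class TestSqHits:
    def base_abund(self, design, sq_a=0.005):
        vals = {"inp1": [0.005, 0.795, 0.2], "inp2": [0.005, 0.795, 0.2]}
        for m in design.mice:
            for c in (1, 2, 3):
                vals[f"{m}_sq{c}"] = [sq_a, 0.795 + 0.005 - sq_a, 0.2]
            for l in (1, 2):
                vals[f"{m}_met{l}"] = [0.005, 0.795, 0.2]
        return abundance_frame(design, vals)

    def test_hit_at_exact_threshold_inclusive(self):
        design = toy_design()
        abund = self.base_abund(design, sq_a=0.5)  # exactly 100x input of 0.005
        enr = enrichment_table(abund, design)
        hits = call_sq_hits(enr, design, fold_threshold=100.0).set_index("orf_id")
        assert hits.loc["A", "is_hit"]
        assert hits.loc["A", "pct_positive_mice"] == pytest.approx(100.0)
        assert not hits.loc["B", "is_hit"]

    def test_no_enrichment_no_hits(self):
        design = toy_design()
        enr = enrichment_table(self.base_abund(design), design)
        hits = call_sq_hits(enr, design)
        assert not hits["is_hit"].any()

    def test_no_sq_samples_warns_empty(self):
        design = toy_design()
        enr = enrichment_table(self.base_abund(design), design)
        met_only = enr[enr["tissue"] != "sq_tumor"]
        with pytest.warns(UserWarning, match="no SQ"):
            hits = call_sq_hits(met_only, design)
        assert hits.empty

    def test_matches_direct_rule_evaluation(self, rng):
        """Randomized enrichment tables reproduce a brute-force reading of the
        SQ rule: any sample >= threshold makes the mouse positive, any positive
        mouse makes the hit."""
        design = toy_design()
        for _ in range(10):
            vals = {}
            for s in design.samples["sample_id"]:
                x = rng.dirichlet([0.3, 0.3, 0.3])
                vals[s] = x
            abund = abundance_frame(design, vals)
            enr = enrichment_table(abund, design)
            thr = rng.uniform(1.5, 20)
            hits = call_sq_hits(enr, design, fold_threshold=thr)
            sq = enr[(enr["tissue"] == "sq_tumor") & ~enr["dropout"]]
            for orf in hits["orf_id"]:
                sub = sq[sq["orf_id"] == orf]
                mice_pos = {
                    m for m, g in sub.groupby("mouse_id") if (g["enrichment"] >= thr).any()
                }
                expected = len(mice_pos) >= 1
                assert bool(hits.set_index("orf_id").loc[orf, "is_hit"]) == expected


class TestMetHits:
    def make_enr(self, design, positive_samples, orf="A"):
        """Abundance where `orf` dominates the given met samples."""
        vals = {}
        for s in design.samples["sample_id"]:
            if s in positive_samples:
                vals[s] = [0.9, 0.05, 0.05]
            else:
                vals[s] = [0.01, 0.6, 0.39] if not s.startswith("inp") else [0.1, 0.6, 0.3]
        vals["inp1"] = [0.1, 0.6, 0.3]
        vals["inp2"] = [0.1, 0.6, 0.3]
        return enrichment_table(abundance_frame(design, vals), design)

    def test_two_samples_one_mouse_not_a_hit(self):
        design = toy_design()
        enr = self.make_enr(design, {"m1_met1", "m1_met2"})
        hits = call_met_hits(enr, design)
        a = hits[hits["orf_id"] == "A"]
        assert not a["is_hit"].any()
        assert a["n_positive_mice"].iloc[0] == 1

    def test_two_samples_two_mice_is_a_hit(self):
        design = toy_design()
        enr = self.make_enr(design, {"m1_met1", "m2_met2"})
        hits = call_met_hits(enr, design).set_index("orf_id")
        assert hits.loc["A", "is_hit"]

    def test_detection_floor_suppresses_noise_calls(self):
        design = toy_design(n_mice=2)
        vals = {s: [0.004, 0.796, 0.2] for s in design.samples["sample_id"]}
        vals["inp1"] = [0.001, 0.799, 0.2]
        vals["inp2"] = [0.001, 0.799, 0.2]
        enr = enrichment_table(abundance_frame(design, vals), design, detection_floor=0.01)
        # A is 4x enriched everywhere but sits below the detection floor
        hits = call_met_hits(enr, design)
        assert hits[hits["orf_id"] == "A"].empty or not hits.set_index("orf_id").loc["A", "is_hit"]

    def test_rule_monotonicity(self, rng):
        design = toy_design()
        vals = {s: rng.dirichlet([0.5, 0.5, 0.5]) for s in design.samples["sample_id"]}
        enr = enrichment_table(abundance_frame(design, vals), design)

        def hitset(**kw):
            h = call_met_hits(enr, design, **kw)
            return set(h.loc[h["is_hit"], "orf_id"]) if not h.empty else set()

        assert hitset(min_mice=3) <= hitset(min_mice=2) <= hitset(min_mice=1)
        assert hitset(min_met_samples=4) <= hitset(min_met_samples=2)
        assert hitset(enrichment_floor=5.0) <= hitset(enrichment_floor=1.0)


class TestClassify:
    def frame(self, orfs, hit=True):
        return pd.DataFrame({"orf_id": list(orfs), "is_hit": [hit] * len(orfs)})

    def test_set_algebra(self):
        out = classify_hits(self.frame("AB"), self.frame("BC"))
        got = dict(zip(out["orf_id"], out["hit_class"]))
        assert got == {"A": "sq", "B": "both", "C": "met"}

    def test_empty_met_side(self):
        out = classify_hits(self.frame("AB"), self.frame(""))
        assert set(out["hit_class"]) == {"sq"}

    def test_matches_set_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            sq = set(rng.choice(list("ABCDEFGH"), rng.integers(0, 6), replace=False))
            met = set(rng.choice(list("ABCDEFGH"), rng.integers(0, 6), replace=False))
            out = classify_hits(self.frame(sorted(sq)), self.frame(sorted(met)))
            both = {r.orf_id for r in out.itertuples() if r.hit_class == "both"}
            assert both == sq & met
            assert set(out["orf_id"]) == sq | met
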