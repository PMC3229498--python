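"""IUPAC scanning, occupancy, positional windows, background envelopes."""

import numpy as np
import pytest

from riboclass import (
    MotifPattern,
    MotifPlantingDesign,
    SITE_II,
    TELO_BOX,
    background_envelope,
    class_occupancy,
    enrichment_calls,
    generate_promoters,
    scan,
)
from riboclass.synthetic import IUPAC_CODES


def naive_matches(seq, motif):
    """Position-by-position oracle; N in sequence only matches motif N."""
    seq = seq.upper()
    out = []
    for i in range(len(seq) - len(motif) + 1):
        ok = True
        for c, m in zip(seq[i : i + len(motif)], motif.upper()):
            allowed = IUPAC_CODES[m] + ("N" if m == "N" else "")
            if c not in allowed:
                ok = False
                break
        if ok:
            out.append(i - len(seq))
    return out


class TestScan:
    def test_site_ii_hit_at_minus_seven(self):
        prof = scan([("p1", "TTTTTTTTTAAGCCCA")], SITE_II)
        assert prof.hits["p1"] == [-7]

    def test_telo_box_w_expansion(self):
        prof = scan([("p1", "GGGGAAACCCTAGGGG")], TELO_BOX)
        assert len(prof.hits["p1"]) == 1

    def test_overlapping_matches_all_reported(self):
        # AAAA contains two AAA starts at -4 and -3... use AA motif on AAAA
        prof = scan([("p1", "CAAAA")], MotifPattern("m", "AAA", -3, 1))
        assert prof.hits["p1"] == [-4, -3]

    def test_n_in_sequence_never_matches(self):
        prof = scan([("p1", "TTANGCCCATT")], SITE_II)
        assert prof.hits["p1"] == []

    def test_truncation_to_last_kilobase(self, rng):
        tail = "".join(rng.choice(list("ACGT"), size=999)) + "T"
        seq_short = "AAGCCCA" + tail[:993]  # hit inside the window
        seq_long = "AAGCCCA" * 30 + seq_short  # extra 5' copies beyond 1000
        p1 = scan([("a", seq_short)], SITE_II)
        p2 = scan([("b", seq_long)], SITE_II)
        assert p1.occupancy == p2.occupancy
        assert p1.hits["a"] == p2.hits["b"]

    def test_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            scan([("p1", "ACGU")], SITE_II)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            scan([], SITE_II)

    def test_agrees_with_naive_matcher(self, rng):
        # ~10^4 positions of random sequence, GC-skewed to yield hits
        for motif in (SITE_II, TELO_BOX, MotifPattern("x", "NRYSWK", -50, 10)):
            seqs = [
                ("p%d" % i, "".join(rng.choice(list("ACGTN"),
                                               p=[0.3, 0.25, 0.25, 0.18, 0.02],
                                               size=500)))
                for i in range(20)
            ]
            prof = scan(seqs, motif)
            for pid, seq in seqs:
                assert prof.hits[pid] == naive_matches(seq, motif.iupac)

    def test_windowed_never_exceeds_occupancy(self, rng):
        design = MotifPlantingDesign(n_promoters=200, plant_fraction=0.5,
                                     position_sd=200, seed=3)
        records, _ = generate_promoters(design)
        prof = scan(records, SITE_II)
        assert prof.windowed_occupancy <= prof.occupancy

    def test_histogram_sums_to_hit_count(self, rng):
        design = MotifPlantingDesign(n_promoters=100, plant_fraction=0.8, seed=5)
        records, _ = generate_promoters(design)
        prof = scan(records, SITE_II)
        assert prof.histogram.sum() == sum(len(h) for h in prof.hits.values())

    def test_planted_occupancy_and_window_capture(self):
        design = MotifPlantingDesign(
            n_promoters=2000, motif="ARGCCCA", plant_fraction=0.75,
            position_mean=-70, position_sd=10, seed=11,
        )
        records, truth = generate_promoters(design)
        prof = scan(records, SITE_II)
        # chance occupancy on top of the planted 0.75, at the design's
        # background base composition (GC 0.36)
        pa = pt = (1 - 0.36) / 2
        pc = pg = 0.36 / 2
        q = pa * (pa + pg) * pg * pc**3 * pa
        chance = 1 - (1 - q) ** (1000 - 6)
        expect = 0.75 + (1 - 0.75) * chance
        sd = np.sqrt(expect * (1 - expect) / 2000)
        assert abs(prof.occupancy - expect) <= 3 * sd
        # the -70 +/- 25 window must capture nearly every planted motif
        planted = truth[truth["planted"]]
        lo, hi = SITE_II.window
        captured = [
            any(lo <= o <= hi for o in prof.hits[pid])
            for pid in planted.index
        ]
        assert np.mean(captured) >= 0.95


class TestClassOccupancy:
    def test_full_and_empty_classes(self):
        full = scan([("a", "T" * 100 + "AAGCCCA" + "T" * 63)], SITE_II)
        empty = scan([("b", "T" * 170)], SITE_II)
        table = class_occupancy({"hitful": full, "hitless": empty})
        by_class = table.set_index("class")
        assert by_class.loc["hitful", "occupancy_pct"] == 100
        assert by_class.loc["hitless", ["occupancy_pct", "windowed_pct"]].tolist() == [0, 0]

    def test_matches_naive_recount(self, rng):
        design = MotifPlantingDesign(n_promoters=50, plant_fraction=0.4, seed=7)
        records, _ = generate_promoters(design)
        prof = scan(records, SITE_II)
        table = class_occupancy({"c": prof}).set_index("class")
        n_occ = sum(1 for _, s in records if naive_matches(s, SITE_II.iupac))
        assert table.loc["c", "occupancy_pct"] == round(100 * n_occ / 50 + 1e-9)
        assert table.loc["c", "n_promoters"] == 50


class TestBackgroundEnvelope:
    def test_identical_pool_collapses(self):
        seq = "T" * 500 + "AAGCCCA" + "T" * 493
        pool = [(f"p{i}", seq) for i in range(30)]
        env = background_envelope(pool, SITE_II, set_size=10, n_resamples=50, seed=0)
        assert np.all(env.sd == 0)
        assert np.allclose(env.lower, env.upper)

    def test_fixed_seed_reproducible(self, rng):
        design = MotifPlantingDesign(n_promoters=80, plant_fraction=0.0, seed=13)
        pool, _ = generate_promoters(design)
        e1 = background_envelope(pool, SITE_II, 20, n_resamples=40, seed=9)
        e2 = background_envelope(pool, SITE_II, 20, n_resamples=40, seed=9)
        assert np.array_equal(e1.mean, e2.mean) and np.array_equal(e1.sd, e2.sd)

    def test_pool_too_small_rejected(self):
        with pytest.raises(ValueError):
            background_envelope([("a", "ACGT" * 50)], SITE_II, set_size=5)


class TestEnrichmentCalls:
    def test_profile_equal_to_mean_is_within(self):
        design = MotifPlantingDesign(n_promoters=60, plant_fraction=0.0, seed=2)
        pool, _ = generate_promoters(design)
        env = background_envelope(pool, SITE_II, set_size=60, n_resamples=30, seed=2)
        prof = scan(pool, SITE_II)
        # full pool scanned vs envelope of full-size resamples: identical
        flags = enrichment_calls(prof, env)
        assert all(f == "within" for f in flags)

    def test_zero_histogram_below_positive_floor(self):
        seq_hit = "T" * 500 + "AAGCCCA" + "T" * 493
        pool = [(f"p{i}", seq_hit) for i in range(30)]
        env = background_envelope(pool, SITE_II, 10, n_resamples=20, seed=1)
        prof = scan([("q", "T" * 1000)], SITE_II)
        flags = enrichment_calls(prof, env)
        hit_bin = (-500 + 1000) // 50  # the pool's single hit sits at -500
        assert flags[hit_bin] == "below"

    def test_binning_mismatch_rejected(self):
        design = MotifPlantingDesign(n_promoters=20, plant_fraction=0.0, seed=4)
        pool, _ = generate_promoters(design)
        env = background_envelope(pool, SITE_II, 10, n_resamples=10, seed=4)
        prof = scan(pool, SITE_II, bin_width=100)
        with pytest.raises(ValueError):
            enrichment_calls(prof, env)

    def test_planted_window_flagged_above(self):
        planted_design = MotifPlantingDesign(
            n_promoters=60, motif="ARGCCCA", plant_fraction=1.0,
            position_mean=-70, position_sd=10, seed=21,
        )
        free_design = MotifPlantingDesign(
            n_promoters=60, plant_fraction=0.0, seed=22,
        )
        pool_design = MotifPlantingDesign(
            n_promoters=400, plant_fraction=0.0, seed=23,
        )
        planted, _ = generate_promoters(planted_design)
        free, _ = generate_promoters(free_design)
        pool, _ = generate_promoters(pool_design)
        env = background_envelope(pool, SITE_II, set_size=60,
                                  n_resamples=300, seed=23)
        flags_planted = enrichment_calls(scan(planted, SITE_II), env)
        flags_free = enrichment_calls(scan(free, SITE_II), env)
        planted_bin = (-70 + 1000) // 50  # bin holding offsets -100..-51
        assert flags_planted[planted_bin] == "above"
        assert np.mean([f == "within" for f in flags_free]) >= 0.95
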