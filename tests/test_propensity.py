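"""Window extraction, propensity maps, binning and per-length profiles."""

import logging
import random

import numpy as np
import pytest

from mtmisalign.genome import Breakpoint, MtGenome
from mtmisalign.propensity import (
    LengthGrid,
    PropensityEngine,
    PropensityMap,
    bin_map,
    breakpoint_profile,
    extract_window,
    position_pair_propensity,
)
from mtmisalign.thermo import duplex_partition_function, oracle_partition_function
from mtmisalign.genome import reverse_complement


def sterile_genome_with_repeat(lstar: int, seed: int = 3,
                               p5: int = 800, p3: int = 2200) -> MtGenome:
    """A genome where only a planted l*-repeat spanning (p5, p3) can hybridize.

    Background: the 5' region is poly-A and the 3' region poly-C, and the
    repeat core uses only G/T, so the sole Watson-Crick pairs in the window
    are the diagonal core-vs-core matches (helix ends must be WC, so
    mismatch-only background cannot hybridize either).
    """
    rng = random.Random(seed)
    L = 3000
    seq = ["A"] * L
    for q in range(p3 - 300, p3 + 300):
        seq[q - 1] = "C"

    def shifted_match_run(s):
        worst = 0
        for d in range(1, len(s)):
            run = best = 0
            for i in range(len(s) - d):
                run = run + 1 if s[i] == s[i + d] else 0
                best = max(best, run)
            worst = max(worst, best)
        return worst

    # aperiodic core: avoid shifted self-matches that would create
    # off-diagonal duplexes at other lengths
    core = min(
        ("".join(rng.choice("GT") for _ in range(lstar)) for _ in range(400)),
        key=shifted_match_run,
    )
    off = lstar // 2
    seq[p5 - 1 - off : p5 - 1 - off + lstar] = core
    seq[p3 - 1 - off : p3 - 1 - off + lstar] = core
    return MtGenome(f"sterile{lstar}", "".join(seq))


class TestLengthGrid:
    def test_default_grid(self):
        assert LengthGrid().lengths == (0, 5, 10, 15, 20, 25, 50, 75, 100)

    def test_must_contain_zero_and_increase(self):
        with pytest.raises(ValueError):
            LengthGrid((5, 10))
        with pytest.raises(ValueError):
            LengthGrid((0, 10, 5))


class TestExtractWindow:
    def test_worked_example_intervals(self):
        rng = random.Random(1)
        g = MtGenome("syn", "".join(rng.choice("ACGT") for _ in range(16569)))
        w = extract_window(g, Breakpoint(6329, 13993), W=100)
        assert w.L_interval == (6229, 6429)
        assert w.H_interval == (13893, 14093)
        assert len(w.L_window) == len(w.H_window) == 201
        # center offsets map to the breakpoint
        assert w.L_window[100] == g.sequence[6329 - 1]
        assert w.H_window[100] == reverse_complement(g.sequence[13993 - 1])

    def test_wraparound_origin(self, random_genome):
        w = extract_window(random_genome, Breakpoint(50, 1500), W=100)
        assert len(w.L_window) == 201
        assert w.L_interval == (2950, 150)
        # stitched across the origin
        assert w.L_window == (
            random_genome.sequence[2949:] + random_genome.sequence[:150]
        )

    def test_w1_gives_3nt_windows(self, random_genome):
        w = extract_window(random_genome, Breakpoint(500, 1500), W=1)
        assert len(w.L_window) == len(w.H_window) == 3

    def test_h_window_is_reverse_complement(self, random_genome):
        w = extract_window(random_genome, Breakpoint(500, 1500), W=10)
        assert w.H_window == reverse_complement(random_genome.sequence[1489:1510])


class TestPositionPairPropensity:
    def test_l5_sums_exactly_25_duplexes(self, random_genome, params):
        """The l=5 propensity of a pair is the sum of the 5x5 overlapping
        duplex partition functions, summed explicitly here."""
        bp = Breakpoint(700, 2100)
        w = extract_window(random_genome, bp, W=100)
        i, j, l = 3, -7, 5
        g = random_genome
        terms = []
        for a in range(l):
            segL = g.sequence[bp.p5 + i - l + a : bp.p5 + i + a]
            for b in range(l):
                ref3 = g.sequence[bp.p3 + j - l + b : bp.p3 + j + b]
                terms.append(
                    duplex_partition_function(
                        segL, reverse_complement(ref3), params
                    ).Z
                )
        assert len(terms) == 25
        assert position_pair_propensity(w, i, j, l, params) == pytest.approx(
            sum(terms), rel=1e-9
        )

    def test_l1_has_no_admissible_duplex(self, random_genome, params):
        w = extract_window(random_genome, Breakpoint(700, 2100), W=100)
        assert position_pair_propensity(w, 0, 0, 1, params) == 0.0

    def test_l3_matches_enumeration_oracle(self, random_genome, params):
        bp = Breakpoint(700, 2100)
        w = extract_window(random_genome, bp, W=100)
        g = random_genome
        expected = 0.0
        for a in range(3):
            segL = g.sequence[bp.p5 - 3 + a : bp.p5 + a]
            for b in range(3):
                ref3 = g.sequence[bp.p3 - 3 + b : bp.p3 + b]
                expected += oracle_partition_function(
                    segL, reverse_complement(ref3), params
                )[0]
        assert position_pair_propensity(w, 0, 0, 3, params) == pytest.approx(
            expected, rel=1e-9
        )

    def test_l0_rejected(self, random_genome, params):
        w = extract_window(random_genome, Breakpoint(700, 2100), W=100)
        with pytest.raises(ValueError):
            position_pair_propensity(w, 0, 0, 0, params)


class TestEngine:
    def test_engine_matches_reference_at_l5(self, random_genome, params):
        bp = Breakpoint(800, 2200)
        engine = PropensityEngine(random_genome, params)
        engine.prepare([bp])
        m = engine.map_for(bp, 5).values
        w = extract_window(random_genome, bp, W=100)
        for i, j in [(0, 0), (-100, -100), (100, 100), (42, -77)]:
            assert m[i + 100, j + 100] == pytest.approx(
                position_pair_propensity(w, i, j, 5, params), rel=1e-9, abs=1e-12
            )

    def test_determinism(self, random_genome, params):
        bp = Breakpoint(800, 2200)
        e1 = PropensityEngine(random_genome, params)
        e1.prepare([bp])
        m1 = e1.map_for(bp, 10).values
        e2 = PropensityEngine(random_genome, params)
        e2.prepare([bp])
        assert np.array_equal(m1, e2.map_for(bp, 10).values)

    def test_shared_cluster_equals_isolated(self, random_genome, params):
        """Evaluating a breakpoint inside a multi-breakpoint cluster gives
        bit-identical maps to evaluating it alone."""
        bps = [Breakpoint(800, 2200), Breakpoint(850, 2250), Breakpoint(900, 2300)]
        eng = PropensityEngine(random_genome, params)
        eng.prepare(bps)
        solo = PropensityEngine(random_genome, params)
        solo.prepare([bps[1]])
        a = eng.map_for(bps[1], 15).values
        b = solo.map_for(bps[1], 15).values
        assert np.allclose(a, b, rtol=1e-9)


class TestBinMap:
    def test_uniform_map_gives_1_over_400(self):
        m = PropensityMap(l=5, values=np.ones((201, 201)))
        binned = bin_map(m, 10)
        assert binned.relative_bins.shape == (20, 20)
        assert np.allclose(binned.relative_bins, 1.0 / 400)

    def test_single_hot_pair(self):
        v = np.zeros((201, 201))
        v[100, 100] = 7.0  # the breakpoint position pair
        binned = bin_map(PropensityMap(l=5, values=v), 10)
        assert binned.relative_bins[binned.breakpoint_bin] == 1.0
        assert binned.breakpoint_bin == (10, 10)

    def test_normalization_and_mass_conservation(self, random_genome, params):
        bp = Breakpoint(800, 2200)
        engine = PropensityEngine(random_genome, params)
        engine.prepare([bp])
        m = engine.map_for(bp, 10)
        binned = bin_map(m, 10)
        assert binned.relative_bins.sum() == pytest.approx(1.0, abs=1e-12)
        assert binned.bins.sum() == pytest.approx(
            m.values[:200, :200].sum(), rel=1e-9
        )

    def test_all_zero_map_falls_back_to_uniform(self, caplog):
        with caplog.at_level(logging.WARNING, logger="mtmisalign"):
            binned = bin_map(PropensityMap(l=5, values=np.zeros((201, 201))), 10)
        assert binned.uniform_fallback
        assert np.allclose(binned.relative_bins, 1.0 / 400)
        assert any("uniform" in r.message for r in caplog.records)


class TestBreakpointProfile:
    def test_l0_is_exactly_uniform(self, random_genome, params):
        prof = breakpoint_profile(
            random_genome, Breakpoint(800, 2200),
            grid=LengthGrid((0, 5, 10)), params=params,
        )
        assert prof[0] == 1.0 / 400

    def test_planted_5_repeat_recovered(self, params):
        g = sterile_genome_with_repeat(5)
        prof = breakpoint_profile(g, Breakpoint(800, 2200), params=params)
        assert max(prof, key=prof.get) == 5

    @pytest.mark.parametrize("lstar", [10, 25])
    def test_planted_long_repeat_signal_and_decay(self, params, lstar):
        """For repeats longer than half a bin the center-bin share peaks at
        or below the planted length (shorter sub-duplexes concentrate the
        same diagonal into fewer bins — see the methods note), but the
        signal at l* itself is far above uniform and decays beyond l*."""
        g = sterile_genome_with_repeat(lstar)
        prof = breakpoint_profile(g, Breakpoint(800, 2200), params=params)
        peak = max(prof, key=prof.get)
        assert 5 <= peak <= lstar
        assert prof[lstar] > 50 * (1.0 / 400)
        beyond = [l for l in prof if l > lstar]
        assert all(prof[l] < prof[lstar] for l in beyond)

    def test_profile_values_are_probabilities(self, random_genome, params):
        prof = breakpoint_profile(
            random_genome, Breakpoint(800, 2200),
            grid=LengthGrid((0, 5, 20)), params=params,
        )
        for v in prof.values():
            assert 0 < v <= 1

    def test_shift_equivariance(self, params):
        """Translating the planted repeat by one bin width moves the maximal
        bin by exactly one index."""
        g0 = sterile_genome_with_repeat(10)
        engine = PropensityEngine(g0, params)
        bp = Breakpoint(800, 2200)
        engine.prepare([bp])
        base = engine.bins_for(bp, 10)
        r0 = np.unravel_index(np.argmax(base.relative_bins), (20, 20))
        # same genome, breakpoint shifted by -10 on the 5' side: the repeat
        # now sits 10 nt downstream of the breakpoint within the window
        bp2 = Breakpoint(790, 2200)
        engine.prepare([bp2])
        shifted = engine.bins_for(bp2, 10)
        r1 = np.unravel_index(np.argmax(shifted.relative_bins), (20, 20))
        assert r1[0] == r0[0] + 1
        assert r1[1] == r0[1]
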