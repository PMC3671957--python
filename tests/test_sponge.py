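"""Seed-site discovery, duplex MFE dynamic program, shuffles, and the null."""

import itertools
import math
import re
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tfmir.energy import default_params, load_params, toy_params
from tfmir.sponge import (
    RnaSequence,
    best_site,
    dinucleotide_shuffle,
    duplex_mfe,
    reverse_complement,
    run_sponge_null,
    seed_sites,
    shuffle_composition,
    sponge_score,
)

warnings.filterwarnings("ignore", message=".*typical miR range.*")

BASES = "ACGU"


def mir(seq, name="m"):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return RnaSequence(name, seq, "mir")


def pairing_energy(pairing, x, y, params):
    """Score one non-crossing pairing from the cost definition (oracle)."""
    if not pairing:
        return 0.0
    for i, j in pairing:
        if not params.can_pair(x[i], y[j]):
            return math.inf
    e = params.init_penalty
    for (i1, j1), (i2, j2) in zip(pairing, pairing[1:]):
        a = i2 - i1 - 1
        b = j1 - j2 - 1
        if a == 0 and b == 0:
            s = params.stack.get((x[i1] + y[j1], x[i2] + y[j2]))
            if s is None:
                return math.inf
            e += s
        elif a == 0 or b == 0:
            if a + b > params.max_loop:
                return math.inf
            e += params.bulge_open + params.bulge_extend * (a + b - 1)
        else:
            if a > params.max_loop or b > params.max_loop:
                return math.inf
            e += params.internal_open + params.internal_extend * (a + b - 2)
    return e


def enumerate_mfe(x, y, params):
    """Brute force: try every antiparallel non-crossing pairing of x and y."""
    n, m = len(x), len(y)
    best = 0.0  # empty structure
    for k in range(1, min(n, m) + 1):
        for isub in itertools.combinations(range(n), k):
            for jsub in itertools.combinations(range(m), k):
                pairing = list(zip(isub, reversed(jsub)))
                best = min(best, pairing_energy(pairing, x, y, params))
    return best


class TestRnaSequence:
    def test_t_mapped_to_u_and_alphabet_enforced(self):
        s = RnaSequence("s", "acgt")
        assert s.bases == "ACGU"
        with pytest.raises(ValueError):
            RnaSequence("s", "ACGX")
        with pytest.raises(ValueError):
            RnaSequence("s", "")

    def test_mir_length_warning(self):
        with pytest.warns(UserWarning, match="18-26"):
            RnaSequence("short", "ACGU", "mir")


class TestSeedSites:
    def test_planted_exact_site_found_once(self):
        m = mir("UAGCUUAUCAGACUGAUGUUGA")  # seed (pos 2-7): AGCUUA
        seed_rc = "UAAGCU"
        t = RnaSequence("t", "C" * 30 + seed_rc + "C" * 30)
        sites = seed_sites(t, m)
        assert len(sites) == 1
        assert sites[0].seed_start == 30

    def test_no_complement_no_candidates(self):
        m = mir("ACGCGCGCAAAAAAAAAAAAAA")  # seed CGCGCG needs G/C content
        t = RnaSequence("t", "A" * 100)
        assert seed_sites(t, m) == []

    def test_planted_sites_match_string_scan_oracle(self, rng):
        m = mir("UGAGGUAGUAGGUUGUAUAGUU")
        seed = m.bases[1:7]
        rc = seed.translate(str.maketrans("ACGU", "UGCA"))[::-1]
        background = "".join(rng.choice(list(BASES), size=2000))
        positions = sorted(rng.choice(np.arange(0, 1900, 40), size=10, replace=False))
        t_list = list(background)
        for p in positions:
            t_list[p : p + 6] = rc
        t = RnaSequence("t", "".join(t_list))
        found = {w.seed_start for w in seed_sites(t, m)}
        oracle = {m.start() for m in re.finditer(f"(?={rc})", t.bases)}
        assert found == oracle
        assert set(positions) <= found

    def test_window_covers_full_mir_plus_margin(self):
        m = mir("UAGCUUAUCAGACUGAUGUUGA")
        rc_seed = "UAAGCU"
        t = RnaSequence("t", "G" * 50 + rc_seed + "G" * 50)
        (w,) = seed_sites(t, m, margin=4)
        # seed at 50; 3' tail (15 nt) extends 5' of it, pos 1 extends 3'
        assert w.start == 50 - 15 - 4
        assert w.end == 50 + 7 + 4


class TestDuplexMfe:
    @pytest.mark.parametrize("L", [4, 7, 9, 12])
    def test_perfect_complement_toy_energy(self, toy, L):
        m = mir(("UGAGGUAGUAGG" * 2)[:L])
        window = reverse_complement(m, "w")
        hit = duplex_mfe(window, m, toy)
        assert hit.delta_g == pytest.approx(-(L - 1))
        assert hit.n_pairs == L

    def test_empty_structure_bound(self, toy):
        # all-A window vs all-A miR: nothing can pair, dG = 0
        hit = duplex_mfe(RnaSequence("w", "AAAA"), mir("AAAA"), toy)
        assert hit.delta_g == 0.0 and hit.pairs == ()

    def test_central_mismatch_matches_enumeration(self, toy_loops):
        m = mir("GGGGAGGGG")
        window = list(reverse_complement(m, "w").bases)
        window[4] = "A"  # mismatch against the central A
        x = "".join(window)
        hit = duplex_mfe(RnaSequence("w", x), m, toy_loops)
        assert hit.delta_g == pytest.approx(enumerate_mfe(x, m.bases, toy_loops))

    @pytest.mark.parametrize("case", range(60))
    def test_matches_enumeration_on_random_pairs(self, case):
        rng = np.random.default_rng(9000 + case)
        params = [
            toy_params(max_loop=2, bulge_open=1.5, bulge_extend=0.5,
                       internal_open=2.0, internal_extend=0.5),
            toy_params(stack_energy=-2.0, init_penalty=1.0, max_loop=1,
                       bulge_open=1.0, bulge_extend=1.0,
                       internal_open=1.0, internal_extend=1.0, allow_gu=True),
            default_params(),
        ][case % 3]
        n, m_len = int(rng.integers(2, 9)), int(rng.integers(2, 9))
        x = "".join(rng.choice(list(BASES), size=n))
        y = "".join(rng.choice(list(BASES), size=m_len))
        hit = duplex_mfe(RnaSequence("w", x), mir(y), params)
        assert hit.delta_g == pytest.approx(enumerate_mfe(x, y, params), abs=1e-9)

    def test_pairs_non_crossing_and_valid(self, rng):
        params = default_params()
        for _ in range(20):
            x = "".join(rng.choice(list(BASES), size=15))
            y = "".join(rng.choice(list(BASES), size=10))
            hit = duplex_mfe(RnaSequence("w", x), mir(y), params)
            for (i1, j1), (i2, j2) in zip(hit.pairs, hit.pairs[1:]):
                assert i1 < i2 and j1 > j2  # antiparallel, non-crossing
            for i, j in hit.pairs:
                assert params.can_pair(x[i], y[j])

    def test_invariant_under_reverse_complement_relabeling(self, rng):
        import dataclasses

        # Watson-Crick pairs map onto Watson-Crick pairs under the relabeling;
        # wobble pairs do not, so they are disabled here
        params = dataclasses.replace(default_params(), allow_gu=False)
        comp = str.maketrans("ACGU", "UGCA")
        for k in range(15):
            x = "".join(rng.choice(list(BASES), size=12))
            y = "".join(rng.choice(list(BASES), size=8))
            dg1 = duplex_mfe(RnaSequence("w", x), mir(y), params).delta_g
            # swap strand roles: the miR's complement plays the window
            x2 = y.translate(comp)[::-1]
            y2 = x.translate(comp)[::-1]
            dg2 = duplex_mfe(RnaSequence("w", x2), mir(y2), params).delta_g
            assert dg1 == pytest.approx(dg2, abs=1e-9)

    def test_weaker_stacks_cannot_lower_energy(self, rng):
        base = toy_params(max_loop=2, bulge_open=1.0, bulge_extend=0.5,
                          internal_open=1.0, internal_extend=0.5)
        weaker = toy_params(stack_energy=-0.5, max_loop=2, bulge_open=1.0,
                            bulge_extend=0.5, internal_open=1.0, internal_extend=0.5)
        for _ in range(15):
            x = "".join(rng.choice(list(BASES), size=10))
            y = "".join(rng.choice(list(BASES), size=8))
            dg_strong = duplex_mfe(RnaSequence("w", x), mir(y), base).delta_g
            dg_weak = duplex_mfe(RnaSequence("w", x), mir(y), weaker).delta_g
            assert dg_weak >= dg_strong - 1e-9

    def test_window_length_cap(self, toy):
        with pytest.raises(ValueError):
            duplex_mfe(RnaSequence("w", "A" * 41), mir("UUUU" * 5), toy)


class TestBestSiteAndScore:
    def test_planted_perfect_site_wins(self, toy):
        m = mir("UAGCUUAUCAGACUGAUGUUGA")
        site = reverse_complement(m).bases
        t = RnaSequence("t", "G" * 20 + site + "G" * 20)
        hit = best_site(t, m, toy)
        assert hit is not None
        assert hit.delta_g == pytest.approx(-(len(m) - 1))

    def test_perfect_beats_mismatched_site(self, toy_loops):
        m = mir("UAGCUUAUCAGACUGAUGUUGA")
        perfect = reverse_complement(m).bases
        mutated = list(perfect)
        mutated[10] = {"A": "C", "C": "A", "G": "A", "U": "G"}[mutated[10]]
        t = RnaSequence("t", "G" * 10 + "".join(mutated) + "G" * 10 + perfect + "G" * 10)
        hit = best_site(t, m, toy_loops)
        start = t.bases.index(perfect)
        assert hit.transcript_window[0] <= start <= hit.transcript_window[1]
        assert hit.delta_g == pytest.approx(-(len(m) - 1))

    def test_no_seed_match_returns_none(self, toy):
        assert best_site(RnaSequence("t", "A" * 60), mir("ACCCCCCCAAAAAAAAAAAAAA"), toy) is None

    def test_sponge_score_sums_per_mir_energies(self, toy):
        m1 = mir("AUGGCAUGC", "m1")
        m2 = mir("GCAUCGAUG", "m2")
        m3 = mir("CCCGGGCCC", "m3")
        t = RnaSequence(
            "t", "AA" + reverse_complement(m1).bases + "UU" + reverse_complement(m2).bases + "AA"
        )
        # two perfect 9-mer sites at 8 each, no site for m3
        assert sponge_score(t, [m1, m2, m3], toy) == pytest.approx(16.0)

    def test_score_persists_under_concatenation(self, toy):
        m = mir("AUGGCAUGC", "m1")
        t1 = RnaSequence("t1", "AA" + reverse_complement(m).bases + "AA")
        t2 = RnaSequence("t2", "GGAGGAGGAGG")
        combined = RnaSequence("t12", t1.bases + t2.bases)
        assert sponge_score(combined, [m], toy) >= sponge_score(t1, [m], toy)


class TestShuffles:
    @given(st.text(alphabet="ACGU", min_size=1, max_size=200), st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_composition_preserved(self, seq, seed):
        s = RnaSequence("s", seq)
        out = shuffle_composition(s, seed)
        assert sorted(out.bases) == sorted(s.bases)

    def test_length_one_identity(self):
        assert shuffle_composition(RnaSequence("s", "G"), 5).bases == "G"

    def test_different_seeds_differ(self, rng):
        s = RnaSequence("s", "".join(rng.choice(list(BASES), size=100)))
        a = shuffle_composition(s, 1).bases
        b = shuffle_composition(s, 2).bases
        assert a != b and sorted(a) == sorted(b)

    @given(st.text(alphabet="ACGU", min_size=3, max_size=120), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_dinucleotide_counts_preserved(self, seq, seed):
        s = RnaSequence("s", seq)
        out = dinucleotide_shuffle(s, seed)
        def counts(b):
            c = {}
            for a, d in zip(b, b[1:]):
                c[a + d] = c.get(a + d, 0) + 1
            return c
        assert counts(out.bases) == counts(s.bases)
        assert out.bases[0] == s.bases[0] and out.bases[-1] == s.bases[-1]


class TestSpongeNull:
    def _params(self):
        return toy_params(allow_gu=False, max_loop=2, bulge_open=2.0,
                          bulge_extend=1.0, internal_open=2.0, internal_extend=1.0)

    def test_planted_sites_beat_null(self, rng):
        mirs = [mir("".join(rng.choice(list(BASES), size=22)), f"m{i}") for i in range(3)]
        background = list(rng.choice(list(BASES), size=600))
        for i, m in enumerate(mirs):
            site = reverse_complement(m).bases
            background[150 * i + 50 : 150 * i + 50 + 22] = site
        t = RnaSequence("t", "".join(background))
        res = run_sponge_null(t, (400, 600), mirs, self._params(), n_shuffles=30, seed=4)
        assert res["full"].empirical_p <= 0.05

    def test_formula_when_true_beats_all_nulls(self, rng):
        m = mir("".join(rng.choice(list(BASES), size=22)), "m")
        background = list(rng.choice(list(BASES), size=300))
        background[100:122] = reverse_complement(m).bases
        t = RnaSequence("t", "".join(background))
        res = run_sponge_null(t, None, [m], self._params(), n_shuffles=10, seed=1)
        r = res["full"]
        if all(s < r.true_score for s in r.null_scores):
            assert r.empirical_p == pytest.approx(1 / 11)
        assert r.empirical_p == pytest.approx(
            (1 + sum(s >= r.true_score for s in r.null_scores)) / 11
        )

    def test_no_planted_sites_p_not_extreme(self, rng):
        # the transcript is itself exchangeable with its shuffles
        mirs = [mir("".join(rng.choice(list(BASES), size=22)), f"m{i}") for i in range(2)]
        ps = []
        for run in range(8):
            t = RnaSequence("t", "".join(rng.choice(list(BASES), size=400)))
            res = run_sponge_null(t, None, mirs, self._params(), n_shuffles=20, seed=run)
            ps.append(res["full"].empirical_p)
        assert min(ps) < 0.95 and max(ps) > 0.1
        assert 0.15 < np.mean(ps) < 0.95

    def test_deterministic_under_seed(self, rng):
        m = mir("".join(rng.choice(list(BASES), size=22)), "m")
        t = RnaSequence("t", "".join(rng.choice(list(BASES), size=300)))
        a = run_sponge_null(t, (200, 300), [m], self._params(), n_shuffles=12, seed=3)
        b = run_sponge_null(t, (200, 300), [m], self._params(), n_shuffles=12, seed=3)
        assert a == b

    def test_invalid_utr_interval_rejected(self, rng):
        m = mir("".join(rng.choice(list(BASES), size=22)), "m")
        t = RnaSequence("t", "".join(rng.choice(list(BASES), size=100)))
        with pytest.raises(ValueError):
            run_sponge_null(t, (90, 200), [m], self._params(), n_shuffles=10, seed=0)


class TestParamsIO:
    def test_default_table_loads_and_is_physical(self):
        p = default_params()
        assert p.stack[("GC", "CG")] == pytest.approx(-3.42)
        for pair1 in ("AU", "UA", "CG", "GC"):
            for pair2 in ("AU", "UA", "CG", "GC"):
                assert p.stack[(pair1, pair2)] <= 0
        # symmetry stack(P,Q) == stack(rev Q, rev P)
        for (a, b), e in p.stack.items():
            assert p.stack[(b[::-1], a[::-1])] == pytest.approx(e)

    def test_round_trip_through_file(self, tmp_path):
        p = default_params()
        path = tmp_path / "params.tsv"
        lines = [f"init_penalty\t{p.init_penalty}", f"bulge_open\t{p.bulge_open}",
                 f"bulge_extend\t{p.bulge_extend}", f"internal_open\t{p.internal_open}",
                 f"internal_extend\t{p.internal_extend}",
                 f"allow_gu\t{str(p.allow_gu).lower()}", f"max_loop\t{p.max_loop}"]
        lines += [f"stack\t{a}\t{b}\t{e}" for (a, b), e in p.stack.items()]
        path.write_text("\n".join(lines) + "\n")
        q = load_params(path)
        assert q.stack == p.stack and q.init_penalty == p.init_penalty
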