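import numpy as np
import pytest

from microclip.core import MatureMiRNA, revcomp
from microclip.duplex import (
    BINDING_TYPES,
    SITE_EXTRA_3P,
    SITE_EXTRA_5P,
    Duplex,
    binding_vector,
    classify_binding,
    dedupe_candidates,
    domain_matches,
    eval_structure_energy,
    fold_duplex,
    scan_mres,
)

RNG = np.random.default_rng(42)


def rand_mirna(rng, name="mir", length=22):
    return MatureMiRNA(name, "".join(rng.choice(list("ACGT"), size=length)))


# ---------------------------------------------------------------------------
# scanning


def test_planted_nine_mer_site_yields_one_candidate():
    m = rand_mirna(np.random.default_rng(0))
    site = revcomp(m.sequence[1:9]) + "A"  # pairs 2-9, A opposite position 1
    seq = "C" * 25 + site + "C" * 10
    cands = scan_mres(seq, [m])
    assert len(cands) == 1
    c = cands[0]
    d = fold_duplex(
        m, seq[c.start : c.end], c.register - c.start,
        [(i - c.start, j) for i, j in c.seed_pairs],
    )
    assert d.binding_type_code == 1
    assert BINDING_TYPES[d.binding_type_code] == "9mer"


def test_poly_a_cluster_has_no_candidates():
    m = MatureMiRNA("let7-like", "UGAGGUAGUAGGUUGUAUAGUU")
    assert scan_mres("A" * 300, [m]) == []


def test_scan_equals_exhaustive_window_enumeration():
    from _oracles import oracle_scan

    rng = np.random.default_rng(7)
    mirnas = [rand_mirna(rng, f"m{i}") for i in range(5)]
    for trial in range(10):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        got = {(c.mirna.name, c.register) for c in scan_mres(seq, mirnas)}
        assert got == oracle_scan(seq, mirnas)


def test_scan_skips_windows_with_ambiguous_bases():
    m = MatureMiRNA("mirX", "UGAGGUAGUAGGUUGUAUAGUU")
    site = revcomp(m.sequence[1:8]) + "A"
    seq = "C" * 25 + site + "C" * 10
    with_n = seq[:30] + "N" + seq[31:]
    with pytest.warns(UserWarning):
        assert scan_mres(with_n, [m]) == []


# ---------------------------------------------------------------------------
# folding


def test_fully_complementary_duplex_is_all_paired_and_stable():
    rng = np.random.default_rng(1)
    m = rand_mirna(rng)
    d = fold_duplex(m, revcomp(m.sequence))
    assert d is not None
    assert d.mirna_pairing_vector.all() and d.site_pairing_vector.all()
    assert d.bulges == 0 and d.internal_loops == 0
    assert d.duplex_energy < 0
    assert d.dangling_end_len == 0


def test_seed_only_duplex_pairs_exactly_positions_two_to_eight():
    # crafted so only the seed can pair: positions 9+ are A against an A-rich
    # site, position 1 is C against an A
    m = MatureMiRNA("seedonly", "C" + "GGCGGCG" + "A" * 14)
    site = "A" * 14 + revcomp(m.sequence[1:8]) + "A"
    i1 = len(site) - 1
    seed_pairs = [(i1 - (j - 1), j) for j in range(2, 9)]
    d = fold_duplex(m, site, register=i1, forced_pairs=seed_pairs)
    assert d is not None
    assert sorted(d.pair_map) == list(range(2, 9))
    assert d.mirna_pairing_vector[1:8].all()
    assert d.mirna_pairing_vector[8:].sum() == 0
    assert d.dangling_end_len == len(m) - 8


# Turner/Xia Watson-Crick stack free energies at 37C, canonical key =
# lexicographic min of (step, revcomp(step)); helix init and AU-end terms.
_STACK = {
    "AA": -0.93, "AT": -1.10, "TA": -1.33, "AG": -2.08, "CA": -2.11,
    "AC": -2.24, "GA": -2.35, "CG": -2.36, "CC": -3.26, "GC": -3.42,
}
_INIT, _AU_END = 4.09, 0.45


def _nn_energy_full_helix(mirna_seq):
    e = _INIT
    for i in range(len(mirna_seq) - 1):
        step = mirna_seq[i : i + 2]
        e += _STACK[min(step, revcomp(step))]
    for end in (mirna_seq[0], mirna_seq[-1]):
        if end in "AT":
            e += _AU_END
    return e


def test_energy_matches_independent_nearest_neighbor_rescoring():
    rng = np.random.default_rng(3)
    checked = 0
    for i in range(30):
        m = rand_mirna(rng, f"m{i}", length=int(rng.integers(16, 25)))
        d = fold_duplex(m, revcomp(m.sequence))
        assert d is not None
        if not d.mirna_pairing_vector.all():
            continue  # MFE broke the full helix (possible for weak ends)
        checked += 1
        assert d.duplex_energy == pytest.approx(
            _nn_energy_full_helix(m.sequence), abs=0.5
        )
    assert checked >= 25


def _random_duplexes(seed, n_clusters=30, n_random=120):
    """Duplexes from scan hits on random clusters plus unconstrained folds
    of random site/miRNA pairs."""
    rng = np.random.default_rng(seed)
    mirnas = [rand_mirna(rng, f"m{i}") for i in range(10)]
    out = []
    for _ in range(n_clusters):
        seq = "".join(rng.choice(list("ACGT"), size=150))
        for c in scan_mres(seq, mirnas):
            d = fold_duplex(
                c.mirna, seq[c.start : c.end], c.register - c.start,
                [(i - c.start, j) for i, j in c.seed_pairs],
            )
            if d is not None:
                out.append(d)
    for _ in range(n_random):
        m = mirnas[int(rng.integers(len(mirnas)))]
        site = "".join(rng.choice(list("ACGT"), size=len(m) + 2))
        d = fold_duplex(m, site)
        if d is not None:
            out.append(d)
    return out


def test_paired_counts_balance_and_energy_sign_on_random_duplexes():
    duplexes = _random_duplexes(4)
    assert len(duplexes) >= 100
    for d in duplexes:
        assert d.mirna_pairing_vector.sum() == d.site_pairing_vector.sum()
        assert set(d.mirna_pairing_vector) <= {0, 1}
        assert d.duplex_energy < 0
        assert 1 <= d.binding_type_code <= 12


def test_removing_a_pair_never_lowers_the_evaluated_energy():
    rng = np.random.default_rng(6)
    for i in range(15):
        m = rand_mirna(rng, f"m{i}")
        d = fold_duplex(m, revcomp(m.sequence))
        assert d is not None
        n1 = len(d.site_sequence)
        base = eval_structure_energy(d.site_sequence, m.sequence, d.structure)
        for j, si in list(d.pair_map.items()):
            if d.pair_kind(j) != "WC":
                continue
            chars = list(d.structure)
            chars[si] = "."
            chars[n1 + j - 1] = "."
            e = eval_structure_energy(d.site_sequence, m.sequence, "".join(chars))
            assert e >= base - 1e-6


# ---------------------------------------------------------------------------
# classification


def test_eight_mer_requires_seed_pairing_plus_target_adenine():
    # position 9 is A opposite an A (unpaired), so the perfect 2-8 pairing
    # plus the target adenine classifies as 8mer, not 9mer
    m = MatureMiRNA("eightmer", "T" + "GGCGGCG" + "A" * 14)
    site = "A" * 14 + revcomp(m.sequence[1:8]) + "A"
    i1 = len(site) - 1
    seed_pairs = [(i1 - (j - 1), j) for j in range(2, 9)]
    d = fold_duplex(m, site, register=i1, forced_pairs=seed_pairs)
    assert d.binding_type_code == 2  # 8mer


def test_offset_six_mer_is_positions_three_to_eight():
    # positions 3-8 complementary; position 2 (A) faces a C and cannot pair
    m = MatureMiRNA("offset", "TA" + "GGCGGC" + "A" * 14)
    site = "A" * 14 + revcomp(m.sequence[2:8]) + "CC"
    i1 = len(site) - 1
    pairs = [(i1 - (j - 1), j) for j in range(3, 9)]
    d = fold_duplex(m, site, register=i1, forced_pairs=pairs)
    assert d.binding_type_code == 6
    assert BINDING_TYPES[6] == "offset-6mer"


def _oracle_classify(d: Duplex) -> int:
    """Literal application of the documented binding-type decision tree."""
    L = len(d.mirna)
    kinds = {j: d.pair_kind(j) for j in range(1, L + 1)}
    wc = lambda j: kinds.get(j) == "WC"
    paired = lambda j: kinds.get(j) in ("WC", "GU", "NC") and j in d.pair_map
    a1 = d.opposite_base(1) == "A"
    if all(wc(j) for j in range(2, 9)) and wc(9) and a1:
        return 1
    if all(wc(j) for j in range(2, 9)) and a1:
        return 2
    if all(wc(j) for j in range(2, 9)):
        return 3
    if all(wc(j) for j in range(2, 8)) and a1:
        return 4
    if all(wc(j) for j in range(2, 8)):
        return 5
    if all(wc(j) for j in range(3, 9)):
        return 6
    if L >= 14 and all(paired(j) for j in range(4, 15)):
        gus = sum(1 for j in range(4, 15) if kinds.get(j) == "GU")
        if gus == 0:
            return 7
        if gus == 1:
            return 8
    run = best = 0
    for j in range(2, 9):
        run = run + 1 if wc(j) else 0
        best = max(best, run)
    sup = sum(1 for j in range(13, min(16, L) + 1) if j in d.pair_map)
    if sup >= 4 and best >= 4:
        return 10
    if sup >= 4 and sum(1 for j in range(2, 9) if j in d.pair_map) >= 4:
        return 9
    if best >= 4:
        return 11
    return 12


def test_classification_matches_rule_table_oracle_on_random_duplexes():
    duplexes = _random_duplexes(11, n_clusters=60, n_random=520)
    assert len(duplexes) >= 500
    for d in duplexes:
        assert classify_binding(d) == _oracle_classify(d)


def test_classification_is_invariant_to_site_padding():
    m = rand_mirna(np.random.default_rng(12))
    d = fold_duplex(m, revcomp(m.sequence))
    pad = 4
    padded = Duplex(
        mirna=d.mirna,
        site_sequence="C" * pad + d.site_sequence,
        register=d.register + pad,
        structure="." * pad + d.structure,
        mirna_pairing_vector=d.mirna_pairing_vector.copy(),
        site_pairing_vector=np.concatenate(
            [np.zeros(pad, dtype=int), d.site_pairing_vector]
        ),
        pair_map={j: i + pad for j, i in d.pair_map.items()},
        duplex_energy=d.duplex_energy,
    )
    assert classify_binding(padded) == classify_binding(d)


# ---------------------------------------------------------------------------
# domains and vectors


def test_perfect_duplex_domain_counts():
    m = rand_mirna(np.random.default_rng(14))
    d = fold_duplex(m, revcomp(m.sequence))
    dom = domain_matches(d)
    assert (dom.seed_matches, dom.seed_run) == (7, 7)
    assert (dom.central_matches, dom.supplementary_matches) == (4, 4)
    assert dom.tail_matches == len(m) - 16
    assert dom.total_matches == len(m)
    assert dom.total_mismatches == 0
    assert dom.site_matches == len(m)


def test_seed_only_duplex_has_empty_downstream_domains():
    m = MatureMiRNA("seedonly", "C" + "GGCGGCG" + "A" * 14)
    site = "A" * 14 + revcomp(m.sequence[1:8]) + "A"
    i1 = len(site) - 1
    pairs = [(i1 - (j - 1), j) for j in range(2, 9)]
    d = fold_duplex(m, site, register=i1, forced_pairs=pairs)
    dom = domain_matches(d)
    assert dom.seed_matches == 7
    assert dom.central_matches == dom.supplementary_matches == dom.tail_matches == 0


def test_domain_counts_match_vector_recount_on_random_duplexes():
    rng = np.random.default_rng(15)
    mirnas = [rand_mirna(rng, f"m{i}") for i in range(6)]
    def runlen(bits):
        best = run = 0
        for b in bits:
            run = run + 1 if b else 0
            best = max(best, run)
        return best
    for _ in range(30):
        seq = "".join(rng.choice(list("ACGT"), size=120))
        for c in scan_mres(seq, mirnas):
            d = fold_duplex(
                c.mirna, seq[c.start : c.end], c.register - c.start,
                [(i - c.start, j) for i, j in c.seed_pairs],
            )
            if d is None:
                continue
            v = d.mirna_pairing_vector
            dom = domain_matches(d)
            L = len(c.mirna)
            assert dom.seed_matches == int(v[1:8].sum())
            assert dom.central_matches == int(v[8:12].sum())
            assert dom.supplementary_matches == int(v[12:16].sum())
            assert dom.tail_matches == int(v[16:].sum())
            assert dom.longest_run == runlen(v)
            assert dom.total_mismatches == L - int(v.sum())
            assert dom.site_longest_run == runlen(d.site_pairing_vector)


def test_binding_vector_padding_and_truncation():
    m = rand_mirna(np.random.default_rng(16))
    d = fold_duplex(m, revcomp(m.sequence))
    mv, sv = binding_vector(d, width=25)
    assert len(mv) == len(sv) == 25
    assert mv[: len(m)].all() and mv[len(m) :].sum() == 0
    # round trip: the first L entries reproduce the raw vector
    assert (mv[: len(m)] == d.mirna_pairing_vector).all()
    mv10, _ = binding_vector(d, width=10)
    assert (mv10 == d.mirna_pairing_vector[:10]).all()


def test_deduplication_keeps_lowest_energy_within_window():
    m = rand_mirna(np.random.default_rng(17))
    base = fold_duplex(m, revcomp(m.sequence))
    near = fold_duplex(m, revcomp(m.sequence))
    near.site_start = 3
    near.duplex_energy = base.duplex_energy + 5.0
    far = fold_duplex(m, revcomp(m.sequence))
    far.site_start = 40
    kept = dedupe_candidates([base, near, far])
    assert len(kept) == 2
    assert base in kept and far in kept
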