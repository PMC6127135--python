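"""miRNA:MRE duplex formation and binding-type classification.

Candidate miRNA recognition elements (MREs) are found by scanning cluster
sequences (mRNA sense, 5'->3') for seed-side matches across an extended
taxonomy: perfect 6-9mer seed matches, offset 6mers, (im)perfect centered
sites, 3' supplementary and 3' compensatory configurations, and residual
noncanonical pairings. Surviving candidates are co-folded against the miRNA
with ViennaRNA under hard constraints that preserve the scan-time seed pairs
and prohibit intramolecular pairing; energies are minimum free energies in
kcal/mol (dangles disabled, documented model choice).

miRNA positions are 1-based (seed = 2-8). Pairing is antiparallel: miRNA
position j lies opposite site index ``register - (j - 1)`` where ``register``
is the site index opposite miRNA position 1 (i.e. the 3'-most site base the
miRNA faces).

Binding-type ordinal codes (part of the model contract; smaller = stronger
seed match):

====  =======================
code  binding type
====  =======================
1     9mer
2     8mer
3     7mer-m8
4     7mer-A1
5     6mer
6     offset 6mer
7     centered (perfect)
8     centered (imperfect, one GU inside the run)
9     3' supplementary (partial seed + full 13-16 pairing)
10    3' compensatory (seed mismatch/wobble rescued by 13-16 pairing)
11    noncanonical seed (>=4 contiguous pairs in 2-8)
12    noncanonical
====  =======================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .core import MatureMiRNA

BINDING_TYPES = {
    1: "9mer",
    2: "8mer",
    3: "7mer-m8",
    4: "7mer-A1",
    5: "6mer",
    6: "offset-6mer",
    7: "centered-perfect",
    8: "centered-imperfect",
    9: "3p-supplementary",
    10: "3p-compensatory",
    11: "noncanonical-seed",
    12: "noncanonical",
}

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}

DEFAULT_VECTOR_WIDTH = 25
SITE_EXTRA_3P = 1  # site bases retained 3' of the base opposite miRNA pos 1
SITE_EXTRA_5P = 2
DEDUP_DISTANCE = 5


def _is_wc(site_base: str, mirna_base: str) -> bool:
    return _WC.get(mirna_base) == site_base


def _is_gu(site_base: str, mirna_base: str) -> bool:
    return (site_base, mirna_base) in (("G", "T"), ("T", "G"))


def _pairs(site_base: str, mirna_base: str) -> bool:
    return _is_wc(site_base, mirna_base) or _is_gu(site_base, mirna_base)


@dataclass
class MRECandidate:
    """A scan hit: a site window in cluster coordinates plus the register
    (cluster index opposite miRNA position 1) and the seed-side pairs that
    triggered the rule (to be preserved as folding constraints)."""

    mirna: MatureMiRNA
    start: int
    end: int
    register: int
    rule: str
    seed_pairs: List[Tuple[int, int]]  # (cluster index, miRNA position)


@dataclass(eq=False)
class Duplex:
    mirna: MatureMiRNA
    site_sequence: str
    register: int  # index within site_sequence opposite miRNA position 1
    structure: str
    mirna_pairing_vector: np.ndarray
    site_pairing_vector: np.ndarray
    pair_map: Dict[int, int]  # miRNA position (1-based) -> site index (0-based)
    duplex_energy: float
    gu_wobbles: int = 0
    bulges: int = 0
    internal_loops: int = 0
    longest_bulge: int = 0
    longest_internal_loop: int = 0
    dangling_end_len: int = 0
    binding_type_code: int = 12
    supplementary: bool = False
    site_start: int = 0  # site window start in cluster coordinates

    def pair_kind(self, j: int) -> Optional[str]:
        """'WC', 'GU' or None for miRNA position j (1-based)."""
        i = self.pair_map.get(j)
        if i is None:
            return None
        sb = self.site_sequence[i]
        mb = self.mirna.sequence[j - 1]
        if _is_wc(sb, mb):
            return "WC"
        if _is_gu(sb, mb):
            return "GU"
        return "NC"

    def opposite_base(self, j: int) -> Optional[str]:
        """Site base opposite miRNA position j by register geometry."""
        i = self.register - (j - 1)
        if 0 <= i < len(self.site_sequence):
            return self.site_sequence[i]
        return None


@dataclass
class DomainDecomposition:
    """13 match descriptors over the seed (2-8), central (9-12),
    supplementary (13-16) and tail (17-3') miRNA domains."""

    seed_matches: int
    central_matches: int
    supplementary_matches: int
    tail_matches: int
    seed_run: int
    central_run: int
    supplementary_run: int
    tail_run: int
    total_matches: int
    longest_run: int
    total_mismatches: int
    site_matches: int
    site_longest_run: int

    def as_dict(self) -> Dict[str, int]:
        return dict(self.__dict__)


# ---------------------------------------------------------------------------
# scanning


def _seed_rules(seq: str, m: str, i1: int) -> List[Tuple[str, List[int]]]:
    """Rules firing for miRNA ``m`` at register ``i1``. Returns
    (rule name, list of miRNA positions whose WC pairs are preserved)."""

    def wc(j: int) -> bool:
        i = i1 - (j - 1)
        return 0 <= i < len(seq) and _is_wc(seq[i], m[j - 1])

    def paired(j: int) -> Tuple[bool, bool]:
        i = i1 - (j - 1)
        if not 0 <= i < len(seq):
            return False, False
        return _pairs(seq[i], m[j - 1]), _is_gu(seq[i], m[j - 1])

    fired: List[Tuple[str, List[int]]] = []
    if all(wc(j) for j in range(2, 8)):
        fired.append(("seed6", [j for j in range(2, 8)]))
    if all(wc(j) for j in range(3, 9)):
        fired.append(("offset6", [j for j in range(3, 9)]))
    # centered: >= 11 contiguous pairs starting at position 4, <= 1 GU inside
    if len(m) >= 14:
        states = [paired(j) for j in range(4, 15)]
        if all(p for p, _ in states) and sum(g for _, g in states) <= 1:
            fired.append(("centered", [j for j in range(4, 15) if wc(j)]))
    # compensatory: >= 4 consecutive WC seed core + all of 13-16 WC
    if len(m) >= 16 and all(wc(j) for j in range(13, 17)):
        best_run: List[int] = []
        run: List[int] = []
        for j in range(2, 9):
            if wc(j):
                run.append(j)
                if len(run) > len(best_run):
                    best_run = list(run)
            else:
                run = []
        if len(best_run) >= 4:
            fired.append(("compensatory", best_run))
    return fired


def scan_mres(
    cluster_seq: str,
    mirnas: Iterable[MatureMiRNA],
    flank: int = 0,
) -> List[MRECandidate]:
    """Scan a sense-strand cluster sequence for candidate MREs.

    Emits one candidate per (register, miRNA) whose seed side satisfies any
    qualifying rule. ``flank`` is accepted for interface compatibility; the
    default pipeline scans the cluster sequence as-is.
    """
    seq = cluster_seq.upper().replace("U", "T")
    bad = set(seq) - set("ACGT")
    candidates: List[MRECandidate] = []
    warned = False
    for mirna in mirnas:
        m = mirna.sequence
        L = len(m)
        for i1 in range(len(seq)):
            lo = max(0, i1 - (L - 1) - SITE_EXTRA_5P)
            hi = min(len(seq), i1 + 1 + SITE_EXTRA_3P)
            window = seq[lo:hi]
            if set(window) - set("ACGT"):
                if not warned and bad:
                    warnings.warn("non-ACGT characters in cluster sequence; windows skipped")
                    warned = True
                continue
            if hi - lo < L - 5:
                continue
            fired = _seed_rules(seq, m, i1)
            if not fired:
                continue
            rule, positions = fired[0]
            seed_pairs = [(i1 - (j - 1), j) for j in positions]
            candidates.append(
                MRECandidate(mirna, lo, hi, i1, rule, seed_pairs)
            )
    return candidates


# ---------------------------------------------------------------------------
# folding


def _to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _make_fold_compound(site_rna: str, mirna_rna: str):
    import RNA

    md = RNA.md()
    md.dangles = 0
    fc = RNA.fold_compound(site_rna + "&" + mirna_rna, md)
    n1, n2 = len(site_rna), len(mirna_rna)
    n = n1 + n2
    nopair = RNA.CONSTRAINT_CONTEXT_NONE | RNA.CONSTRAINT_CONTEXT_NO_REMOVE
    for i in range(1, n + 1):
        hi = n1 if i <= n1 else n
        for j in range(i + 1, hi + 1):
            fc.hc_add_bp(i, j, nopair)
    return fc


def eval_structure_energy(site_seq: str, mirna_seq: str, structure: str) -> float:
    """Free energy (kcal/mol) of a given intermolecular structure,
    nearest-neighbor model, dangles disabled."""
    import RNA

    md = RNA.md()
    md.dangles = 0
    fc = RNA.fold_compound(_to_rna(site_seq) + "&" + _to_rna(mirna_seq), md)
    return float(fc.eval_structure(structure))


def fold_duplex(
    mirna: MatureMiRNA,
    site_seq: str,
    register: Optional[int] = None,
    forced_pairs: Optional[Sequence[Tuple[int, int]]] = None,
) -> Optional[Duplex]:
    """Co-fold miRNA and site under constraints keeping scan-time seed pairs.

    ``register``: site index opposite miRNA position 1 (default: the site
    base ``SITE_EXTRA_3P`` in from the 3' end). ``forced_pairs`` are
    (site index, miRNA position) pairs to enforce. Returns None when no
    structure with negative energy exists.
    """
    import RNA

    site_seq = site_seq.upper().replace("U", "T")
    L = len(mirna)
    if not (L - 5 <= len(site_seq) <= L + 10):
        raise ValueError(
            f"site length {len(site_seq)} outside [{L - 5}, {L + 10}]"
        )
    if register is None:
        register = len(site_seq) - 1 - SITE_EXTRA_3P
    fc = _make_fold_compound(_to_rna(site_seq), _to_rna(mirna.sequence))
    n1 = len(site_seq)
    enforce = RNA.CONSTRAINT_CONTEXT_ALL_LOOPS | RNA.CONSTRAINT_CONTEXT_ENFORCE
    for i, j in forced_pairs or []:
        fc.hc_add_bp(i + 1, n1 + j, enforce)
    structure, energy = fc.mfe()
    if energy >= 0 or energy > 1e4:
        return None
    pt = RNA.ptable(structure)
    pair_map: Dict[int, int] = {}
    for j in range(1, L + 1):
        partner = pt[n1 + j]
        if partner > 0:
            pair_map[j] = partner - 1
    mvec = np.zeros(L, dtype=int)
    svec = np.zeros(n1, dtype=int)
    for j, i in pair_map.items():
        mvec[j - 1] = 1
        svec[i] = 1
    dup = Duplex(
        mirna=mirna,
        site_sequence=site_seq,
        register=register,
        structure=structure,
        mirna_pairing_vector=mvec,
        site_pairing_vector=svec,
        pair_map=pair_map,
        duplex_energy=float(energy),
    )
    _annotate_loops(dup)
    dup.gu_wobbles = sum(1 for j in pair_map if dup.pair_kind(j) == "GU")
    # unpaired miRNA 3'-terminal run
    dangle = 0
    for j in range(L, 0, -1):
        if j in pair_map:
            break
        dangle += 1
    dup.dangling_end_len = dangle
    dup.binding_type_code = classify_binding(dup)
    return dup


def _annotate_loops(dup: Duplex) -> None:
    """Count bulges (asymmetric unpaired runs) and internal loops
    (symmetric unpaired runs) between consecutive intermolecular pairs."""
    items = sorted(dup.pair_map.items())  # ascending miRNA position
    bulges = loops = 0
    longest_b = longest_l = 0
    for (j1, i1), (j2, i2) in zip(items, items[1:]):
        gap_m = j2 - j1 - 1
        gap_s = i1 - i2 - 1
        if gap_m < 0 or gap_s < 0:
            continue  # crossing pairs cannot occur in a nested structure
        if gap_m == 0 and gap_s == 0:
            continue
        if gap_m == gap_s:
            loops += 1
            longest_l = max(longest_l, gap_m)
        else:
            bulges += 1
            longest_b = max(longest_b, gap_m, gap_s)
    dup.bulges = bulges
    dup.internal_loops = loops
    dup.longest_bulge = longest_b
    dup.longest_internal_loop = longest_l


# ---------------------------------------------------------------------------
# classification


def classify_binding(dup: Duplex) -> int:
    """Ordinal binding-type code (see module docstring table).

    The strongest (smallest) applicable code wins; the 3' supplementary
    flag is set independently when a >=6mer seed is accompanied by >=4
    pairs within miRNA positions 13-16.
    """
    L = len(dup.mirna)

    def wc(j: int) -> bool:
        return dup.pair_kind(j) == "WC"

    def paired(j: int) -> bool:
        return j in dup.pair_map

    a1 = dup.opposite_base(1) == "A"
    sup_pairs = sum(1 for j in range(13, min(16, L) + 1) if paired(j))
    seed_wc_27 = all(wc(j) for j in range(2, 8))
    seed_wc_28 = all(wc(j) for j in range(2, 9))

    code = 12
    if seed_wc_28 and wc(9) and a1:
        code = 1
    elif seed_wc_28 and a1:
        code = 2
    elif seed_wc_28:
        code = 3
    elif seed_wc_27 and a1:
        code = 4
    elif seed_wc_27:
        code = 5
    elif all(wc(j) for j in range(3, 9)):
        code = 6
    else:
        # centered: >= 11 contiguous pairs starting at position 4, <= 1 GU
        if L >= 14 and all(paired(j) for j in range(4, 15)):
            gus = sum(1 for j in range(4, 15) if dup.pair_kind(j) == "GU")
            if gus == 0:
                code = 7
            elif gus == 1:
                code = 8
        if code == 12:
            run = best = 0
            for j in range(2, 9):
                run = run + 1 if wc(j) else 0
                best = max(best, run)
            if sup_pairs >= 4 and best >= 4:
                code = 10
            elif sup_pairs >= 4 and sum(1 for j in range(2, 9) if paired(j)) >= 4:
                code = 9
            elif best >= 4:
                code = 11
    dup.supplementary = code <= 6 and sup_pairs >= 4
    return code


def domain_matches(dup: Duplex) -> DomainDecomposition:
    """Per-domain total/consecutive match counts from the pairing vectors."""
    L = len(dup.mirna)
    vec = dup.mirna_pairing_vector

    def longest_run(bits) -> int:
        best = run = 0
        for b in bits:
            run = run + 1 if b else 0
            best = max(best, run)
        return best

    def dom(a: int, b: int):  # miRNA positions a..b inclusive
        bits = vec[a - 1 : min(b, L)]
        return int(bits.sum()), longest_run(bits)

    seed_t, seed_r = dom(2, 8)
    cen_t, cen_r = dom(9, 12)
    sup_t, sup_r = dom(13, 16)
    tail_t, tail_r = dom(17, L) if L >= 17 else (0, 0)
    total = int(vec.sum())
    svec = dup.site_pairing_vector
    return DomainDecomposition(
        seed_matches=seed_t,
        central_matches=cen_t,
        supplementary_matches=sup_t,
        tail_matches=tail_t,
        seed_run=seed_r,
        central_run=cen_r,
        supplementary_run=sup_r,
        tail_run=tail_r,
        total_matches=total,
        longest_run=longest_run(vec),
        total_mismatches=L - total,
        site_matches=int(svec.sum()),
        site_longest_run=longest_run(svec),
    )


def binding_vector(dup: Duplex, width: int = DEFAULT_VECTOR_WIDTH):
    """miRNA-side and site-side binary vectors padded/truncated to a fixed
    model width for classifier consumption."""

    def fit(v: np.ndarray) -> np.ndarray:
        if len(v) >= width:
            return v[:width].astype(int)
        return np.concatenate([v, np.zeros(width - len(v), dtype=int)])

    return fit(dup.mirna_pairing_vector), fit(dup.site_pairing_vector)


def dedupe_candidates(duplexes: List[Duplex]) -> List[Duplex]:
    """Collapse same-miRNA duplexes whose registers lie within
    ``DEDUP_DISTANCE`` nt, keeping the lowest-energy one."""
    out: List[Duplex] = []
    by_mirna: Dict[str, List[Duplex]] = {}
    for d in duplexes:
        by_mirna.setdefault(d.mirna.name, []).append(d)
    for group in by_mirna.values():
        group.sort(key=lambda d: d.site_start + d.register)
        kept: List[Duplex] = []
        for d in group:
            if kept and (d.site_start + d.register) - (
                kept[-1].site_start + kept[-1].register
            ) <= DEDUP_DISTANCE:
                if d.duplex_energy < kept[-1].duplex_energy:
                    kept[-1] = d
            else:
                kept.append(d)
        out.extend(kept)
    out.sort(key=lambda d: (d.mirna.name, d.site_start + d.register))
    return out
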