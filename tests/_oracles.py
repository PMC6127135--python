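"""Independent brute-force oracles shared by the unit and acceptance tests.

These re-derive expected results by literal application of the documented
rules, independent of the library's implementation paths.
"""

from microclip.duplex import SITE_EXTRA_3P, SITE_EXTRA_5P

_WC = {"A": "T", "T": "A", "C": "G", "G": "C"}


def oracle_scan(seq, mirnas):
    """Exhaustive window enumeration of qualifying (miRNA, register) hits."""

    hits = set()
    for m in mirnas:
        s = m.sequence
        L = len(s)
        for i1 in range(len(seq)):
            lo = max(0, i1 - (L - 1) - SITE_EXTRA_5P)
            hi = min(len(seq), i1 + 1 + SITE_EXTRA_3P)
            if hi - lo < L - 5 or set(seq[lo:hi]) - set("ACGT"):
                continue

            def wc(j):
                i = i1 - (j - 1)
                return 0 <= i < len(seq) and seq[i] == _WC[s[j - 1]]

            def pairing(j):
                i = i1 - (j - 1)
                if not 0 <= i < len(seq):
                    return False, False
                gu = (seq[i], s[j - 1]) in (("G", "T"), ("T", "G"))
                return seq[i] == _WC[s[j - 1]] or gu, gu

            ok = all(wc(j) for j in range(2, 8)) or all(wc(j) for j in range(3, 9))
            if not ok and L >= 14:
                states = [pairing(j) for j in range(4, 15)]
                ok = all(p for p, _ in states) and sum(g for _, g in states) <= 1
            if not ok and L >= 16 and all(wc(j) for j in range(13, 17)):
                run = best = 0
                for j in range(2, 9):
                    run = run + 1 if wc(j) else 0
                    best = max(best, run)
                ok = best >= 4
            if ok:
                hits.add((m.name, i1))
    return hits
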