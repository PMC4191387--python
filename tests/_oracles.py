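"""Independent brute-force oracles shared by the test modules."""

from snvprofiler.categories import SEQUON_CATEGORIES


def naive_scan(variants, sites, proteome):
    """Exhaustive variant x site double loop re-deriving the disruption rules.

    Kept independent of the scanner's position index: co-location and the
    default rules (every direct replacement disrupts; sequon offsets 0/1/2
    with N-loss, X-to-proline and non-S/T third-position breaks) are
    restated here from first principles.
    """
    pairs = set()
    for v in variants:
        for s in sites:
            if v.accession != s.accession:
                continue
            if s.category in SEQUON_CATEGORIES:
                off = v.position - s.position
                if off not in (0, 1, 2):
                    continue
                if off == 0:
                    hit = v.alt_aa != "N"
                elif off == 1:
                    hit = v.alt_aa == "P"
                else:
                    hit = v.alt_aa not in "ST"
            else:
                if v.position != s.position:
                    continue
                hit = True
            if hit:
                pairs.add((v.key, s.key))
    return pairs
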