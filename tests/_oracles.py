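"""Independent brute-force oracles, deliberately sharing no code with the
package's seed-and-extend path."""

import numpy as np

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(seq: str) -> str:
    return "".join(_COMP[c] for c in reversed(seq))


def exhaustive_hits(catalog, read: str, max_mismatches: int):
    """Every (genome_id, 1-based pos, is_reverse, mismatches) locus where the
    read (or its reverse complement) aligns ungapped with at most
    ``max_mismatches`` substitutions, by scanning every offset of every
    genome on both strands with a sliding-window Hamming count."""
    hits = set()
    rl = len(read)
    for rec in catalog:
        genome = np.frombuffer(rec.sequence.encode(), dtype=np.uint8)
        if len(genome) < rl:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(genome, rl)
        for is_rev, oriented in ((False, read), (True, revcomp(read))):
            q = np.frombuffer(oriented.encode(), dtype=np.uint8)
            mm = (windows != q).sum(axis=1)
            for pos0 in np.nonzero(mm <= max_mismatches)[0]:
                hits.add((rec.genome_id, int(pos0) + 1, is_rev, int(mm[pos0])))
    return hits


def reference_filter_predicate(mapq: int, cigar: str, nm: int) -> bool:
    """Literal restatement of the three post-alignment rules, written
    independently of the package: drop MAPQ below 5, drop any alignment whose
    CIGAR includes an insertion, deletion, skipped region, soft clip or hard
    clip, drop more than three mismatches."""
    if mapq < 5:
        return False
    # walk the CIGAR by hand (no regex, unlike the implementation)
    i = 0
    while i < len(cigar):
        j = i
        while j < len(cigar) and cigar[j].isdigit():
            j += 1
        op = cigar[j]
        if op in "IDNSH":
            return False
        i = j + 1
    if nm > 3:
        return False
    return True
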