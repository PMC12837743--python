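"""Independent brute-force reference implementations used as test oracles.

These deliberately use the most literal possible algorithms (substring
scans, exhaustive enumeration, textbook step-up) and share no code with the
package paths they check.
"""

from typing import List, Sequence

import math

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def brute_force_cuts(sequence: str, motif: str, offset: int) -> List[int]:
    """Cut positions by scanning every substring for the motif."""
    seq = sequence.upper()
    return [
        i + offset
        for i in range(len(seq) - len(motif) + 1)
        if seq[i : i + len(motif)] == motif
    ]


def brute_force_fragments(sequence: str, motif: str, offset: int):
    """(start, end) intervals between cuts, zero-length dropped."""
    cuts = sorted(set(brute_force_cuts(sequence, motif, offset)) | {0, len(sequence)})
    return [(s, e) for s, e in zip(cuts, cuts[1:]) if e > s]


def bh_stepup(pvalues: Sequence[float]) -> List[float]:
    """Textbook Benjamini-Hochberg step-up with monotonicity enforcement."""
    n = len(pvalues)
    order = sorted(range(n), key=lambda i: pvalues[i])
    adj = [0.0] * n
    running_min = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        rank = n - rank_from_end  # 1-based rank of this p-value
        value = pvalues[idx] * n / rank
        running_min = min(running_min, value)
        adj[idx] = min(running_min, 1.0)
    return adj


def pwm_probabilities(counts, pseudocount: float):
    """counts: 4 x L list of lists (A, C, G, T rows)."""
    L = len(counts[0])
    probs = [[0.0] * L for _ in range(4)]
    for j in range(L):
        colsum = sum(counts[b][j] for b in range(4))
        for b in range(4):
            probs[b][j] = (counts[b][j] + pseudocount / 4.0) / (colsum + pseudocount)
    return probs


def score_window_oracle(probs, background, window: str) -> float:
    index = {"A": 0, "C": 1, "G": 2, "T": 3}
    total = 0.0
    for j, base in enumerate(window):
        b = index[base]
        total += math.log2(probs[b][j] / background[b])
    return total


def best_allele_score_oracle(
    counts, pseudocount: float, background, context: str, snp_offset: int, allele: str
):
    """Exhaustive max over all motif windows overlapping the SNP, both strands."""
    probs = pwm_probabilities(counts, pseudocount)
    L = len(counts[0])
    seq = context[:snp_offset] + allele + context[snp_offset + 1 :]
    best = None
    for offset in range(snp_offset - L + 1, snp_offset + 1):
        if offset < 0 or offset + L > len(seq):
            continue
        window = seq[offset : offset + L]
        for oriented in (window, revcomp(window)):
            if "N" in oriented:
                continue
            score = score_window_oracle(probs, background, oriented)
            if best is None or score > best:
                best = score
    return best
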