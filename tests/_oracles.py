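"""Independent brute-force oracles, deliberately separate from the package
implementation paths they check."""

from __future__ import annotations

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_orfs(seq: str, start_codons, stop_codons, min_len_nt: int = 60):
    """Six-frame ORF scan by explicit codon lists (no streaming state).

    Returns a set of (start, end, strand) in forward 0-based half-open
    coordinates, applying the first-start-per-segment rule, the ATG
    promotion rule and the minimum coding-span rule.
    """
    out = set()
    n = len(seq)
    for strand in "+-":
        s = seq if strand == "+" else rc(seq)
        for off in range(3):
            codons = [s[i : i + 3] for i in range(off, n - 2, 3)]
            stop_idx = [i for i, c in enumerate(codons) if c in stop_codons]
            seg_start = 0
            for si in stop_idx:
                starts = [
                    j for j in range(seg_start, si) if codons[j] in start_codons
                ]
                if starts:
                    chosen = starts[0]
                    if codons[chosen] != "ATG":
                        atgs = [k for k in range(chosen, si) if codons[k] == "ATG"]
                        if atgs and (si - atgs[0]) * 3 >= min_len_nt:
                            chosen = atgs[0]
                    if (si - chosen) * 3 >= min_len_nt:
                        a = off + 3 * chosen
                        b = off + 3 * si + 3
                        if strand == "+":
                            out.add((a, b, "+"))
                        else:
                            out.add((n - b, n - a, "-"))
                seg_start = si + 1
    return out


def dp_levenshtein(a: str, b: str) -> int:
    """Quadratic dynamic-programming edit distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
            )
        prev = cur
    return prev[-1]
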