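"""Independent brute-force oracles used to check the library's fast paths.

Everything here is deliberately naive: triple-frame scanning from every
ATG, fragment-concatenation digestion, and exact hypergeometric
summation with integer arithmetic. These stay independent of the code
they verify.
"""

from __future__ import annotations

import math

STOPS = {"TAA", "TAG", "TGA"}


def brute_force_orfs(
    seq: str, min_len_aa: int = 1, nested: bool = False
) -> set[tuple[int, int]]:
    """All (start, end) ATG..stop spans, scanning forward from every ATG.

    A codon containing N aborts the scan from that ATG (untranslatable).
    With ``nested`` False only the 5'-most ATG per (frame, stop) is kept.
    """
    spans = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        j = i
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if "N" in codon:
                break
            if codon in STOPS:
                if (j + 3 - i) // 3 - 1 >= min_len_aa:
                    spans.append((i, j + 3))
                break
            j += 3
    if not nested:
        best: dict[tuple[int, int], int] = {}
        for s, e in spans:
            key = (s % 3, e)
            best[key] = min(best.get(key, s), s)
        spans = [(s, e) for (_f, e), s in best.items()]
    return set(spans)


def brute_force_digest(
    seq: str, max_missed: int = 2, min_len: int = 1, max_len: int = 10**9
) -> set[tuple[str, int]]:
    """All (peptide, missed_cleavages) from concatenating consecutive
    fully-cleaved tryptic fragments."""
    sites = [
        i + 1 for i in range(len(seq) - 1) if seq[i] in "KR" and seq[i + 1] != "P"
    ]
    bounds = [0, *sites, len(seq)]
    frags = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
    out = set()
    for i in range(len(frags)):
        for j in range(i, min(i + max_missed + 1, len(frags))):
            pep = "".join(frags[i : j + 1])
            if min_len <= len(pep) <= max_len:
                out.add((pep, j - i))
    return out


def two_sided_fisher_p(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by summing all tables with
    the same margins whose probability does not exceed the observed one
    (minimum-likelihood convention), in exact integer arithmetic."""
    n = a + b + c + d
    r1, c1 = a + b, a + c

    def prob(x: int) -> float:
        return (
            math.comb(r1, x) * math.comb(n - r1, c1 - x) / math.comb(n, c1)
        )

    p_obs = prob(a)
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    return sum(p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9))


def pooled_t_pvalue(x, y) -> float:
    """Unpaired two-tailed Student's t with pooled variance, from first
    principles (only the distribution function comes from scipy)."""
    import numpy as np
    from scipy.stats import t as tdist

    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    tstat = (x.mean() - y.mean()) / math.sqrt(sp2 * (1 / nx + 1 / ny))
    return 2 * tdist.sf(abs(tstat), nx + ny - 2)
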