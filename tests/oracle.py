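"""Independent brute-force colorspace aligner used as a test oracle.

Deliberately naive: an explicit hard-coded SOLiD di-base matrix (not the
package's XOR codec), string operations, and exhaustive enumeration of
every (precursor, start, insert-length, interpretation) candidate.  Shares
no code with the production aligner.
"""

from __future__ import annotations

# The published SOLiD two-base matrix.
MATRIX = {
    "AA": 0, "AC": 1, "AG": 2, "AT": 3,
    "CA": 1, "CC": 0, "CG": 3, "CT": 2,
    "GA": 2, "GC": 3, "GG": 0, "GT": 1,
    "TA": 3, "TC": 2, "TG": 1, "TT": 0,
}

_FLAG_RANK = {"none": 0, "single_nta": 1, "double_nta": 2}


def _decode_step(prev_base: str, color: int) -> str:
    for b in "ACGT":
        if MATRIX[prev_base + b] == color:
            return b
    raise AssertionError("unreachable")


def oracle_align(
    colors: str,
    primer: str,
    precursors: dict[str, str],
    adaptor: str,
    min_template: int = 15,
    max_insert: int = 32,
    max_mm: int = 1,
    boundary_confirm: int = 2,
):
    """Best hit as (precursor_id, start, template_len, flag, nmm, addition)
    or None; ranking identical in meaning to the production aligner."""
    c = [int(ch) for ch in colors]
    n = len(c)
    a0 = adaptor[0]
    candidates = []
    order = 0
    for pid in sorted(precursors):
        seq = precursors[pid]
        for start in range(1, len(seq) + 1):  # 1-based template start
            order += 1
            for k in range(min_template, min(n - 1, max_insert) + 1):
                # adaptor-vs-adaptor colors past the boundary must also match
                confirm_ok = all(
                    k + 1 + j >= n
                    or c[k + 1 + j] == MATRIX[adaptor[j] + adaptor[j + 1]]
                    for j in range(min(boundary_confirm, len(adaptor) - 1))
                )
                if not confirm_ok:
                    continue
                # expected template colors for insert positions 1..k
                def expected(i: int):  # 1-based insert position
                    pos = start + i - 1  # 1-based precursor position
                    if pos > len(seq):
                        return None
                    prev = primer if i == 1 else seq[pos - 2]
                    return MATRIX[prev + seq[pos - 1]]

                # pure template of length k
                if start + k - 1 <= len(seq):
                    nmm = sum(1 for i in range(1, k + 1) if expected(i) != c[i - 1])
                    boundary = MATRIX[seq[start + k - 2] + a0]
                    if nmm <= max_mm and c[k] == boundary:
                        candidates.append(((nmm, order, -k, 0), (pid, start, k, "none", nmm, "")))
                # template k-1 plus a single addition
                if k - 1 >= min_template and start + k - 2 <= len(seq):
                    nmm = sum(1 for i in range(1, k) if expected(i) != c[i - 1])
                    # the added base sits at insert position k: color c[k-1]
                    a1 = _decode_step(seq[start + k - 3], c[k - 1])
                    pos = start + k - 1
                    nontemplate = pos > len(seq) or seq[pos - 1] != a1
                    if (
                        nmm <= max_mm
                        and nontemplate
                        and c[k] == MATRIX[a1 + a0]
                    ):
                        candidates.append(
                            ((nmm, order, -k, 1), (pid, start, k - 1, "single_nta", nmm, a1))
                        )
                # template k-2 plus a double addition
                if k - 2 >= min_template and start + k - 3 <= len(seq):
                    nmm = sum(1 for i in range(1, k - 1) if expected(i) != c[i - 1])
                    # added bases at insert positions k-1 and k
                    a1 = _decode_step(seq[start + k - 4], c[k - 2])
                    a2 = _decode_step(a1, c[k - 1])
                    pos1, pos2 = start + k - 2, start + k - 1
                    nt1 = pos1 > len(seq) or seq[pos1 - 1] != a1
                    nt2 = pos2 > len(seq) or seq[pos2 - 1] != a2
                    if (
                        nmm <= max_mm
                        and nt1
                        and nt2
                        and c[k] == MATRIX[a2 + a0]
                    ):
                        candidates.append(
                            ((nmm, order, -k, 2), (pid, start, k - 2, "double_nta", nmm, a1 + a2))
                        )
    if not candidates:
        return None
    return min(candidates)[1]
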