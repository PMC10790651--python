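"""Independent straight-line reference for the read-trimming operators.

Deliberately written without reuse of the package implementation: plain
loops, no slicing tricks, one operator after another, so it can serve as an
oracle for quality_trim.  Operator order: adapter clip, headcrop, leading,
trailing, sliding window (cut at first failing window, then strip trailing
low-quality bases), minimum length.
"""

from __future__ import annotations


def reference_trim(
    sequence: str,
    qualities: list[int],
    adapters: list[str],
    leading_q: int,
    trailing_q: int,
    window_len: int,
    window_q: int,
    min_len: int,
    headcrop: int,
):
    assert len(sequence) == len(qualities)
    bases = list(sequence)
    quals = list(qualities)

    # adapter clip: leftmost exact occurrence anywhere, or >=10-base adapter
    # prefix flush with the 3' end
    best = len(bases)
    for adapter in adapters:
        for start in range(0, len(bases) - len(adapter) + 1):
            if "".join(bases[start : start + len(adapter)]) == adapter:
                if start < best:
                    best = start
                break
        for k in range(min(len(adapter), len(bases)), 9, -1):
            tail = "".join(bases[len(bases) - k :])
            if tail == adapter[:k]:
                if len(bases) - k < best:
                    best = len(bases) - k
                break
    bases = bases[:best]
    quals = quals[:best]

    # headcrop
    new_bases, new_quals = [], []
    for i in range(len(bases)):
        if i >= headcrop:
            new_bases.append(bases[i])
            new_quals.append(quals[i])
    bases, quals = new_bases, new_quals

    # leading
    while len(quals) > 0 and quals[0] < leading_q:
        bases.pop(0)
        quals.pop(0)

    # trailing
    while len(quals) > 0 and quals[-1] < trailing_q:
        bases.pop()
        quals.pop()

    # sliding window
    cut_at = None
    i = 0
    while i + window_len <= len(quals):
        total = 0
        for j in range(i, i + window_len):
            total += quals[j]
        if total / window_len < window_q:
            cut_at = i
            break
        i += 1
    if cut_at is not None:
        bases = bases[:cut_at]
        quals = quals[:cut_at]
        while len(quals) > 0 and quals[-1] < window_q:
            bases.pop()
            quals.pop()

    if len(bases) < min_len:
        return None
    return "".join(bases), tuple(quals)
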