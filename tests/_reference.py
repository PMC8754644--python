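"""Independent brute-force reference implementation of the burst-calling
rules, written as a literal step-by-step transcription for use as a test
oracle.  Deliberately naive (pure-Python scalar loops, no vectorization,
no shared code with the package) so that agreement with the package is a
meaningful cross-check.
"""

from __future__ import annotations


def oracle_call_bursts(smoothed, threshold, min_len=5, end_frac=0.55,
                       shift=2):
    """Return [(start, end)] inclusive intervals after shift and filters."""
    s = [float(v) for v in smoothed]
    n = len(s)

    # rule 1 + 2: open at the first above-threshold frame, track the running
    # local peak, close (exclusive) at the first frame below end_frac * peak
    raw = []
    i = 0
    while i < n:
        if s[i] > threshold:
            peak = s[i]
            j = i + 1
            while j < n:
                if s[j] < end_frac * peak:
                    break
                if s[j] > peak:
                    peak = s[j]
                j += 1
            raw.append((i, j))
            i = j
        else:
            i += 1

    out = []
    for a, b in raw:
        # rule 5: discard a burst opening at the very start of detection on
        # a monotonically decreasing run of min_len frames
        if a == 0:
            head = s[:min(min_len, n)]
            decreasing = len(head) >= 2 and all(
                head[k + 1] < head[k] for k in range(len(head) - 1))
            if decreasing:
                continue
        # rule 3: shift two frames later, clamped at the trace end
        na = a + shift
        nb = min(b - 1 + shift, n - 1)
        if na > n - 1:
            continue
        # rule 4: false positives shorter than min_len
        if nb - na + 1 < min_len:
            continue
        # merge on overlap (possible only through end-clamping)
        if out and na <= out[-1][1]:
            na = out.pop()[0]
        out.append((na, nb))
    return out
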