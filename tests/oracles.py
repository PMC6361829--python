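"""Independent reference implementations used only as test oracles.

``oracle_classify`` is a deliberately literal, unoptimised transcription of
the movement-state decision rules: for each sample it re-scans its look-ahead
window with explicit ``any(...)`` loops and walks the rule cascade in order.
It shares no code with ``ethotrack.segmentation.classify_samples`` (which
precomputes next-occurrence indices and runs a compiled loop); agreement
between the two pins the semantics of the state machine.
"""

from __future__ import annotations

import math


def _vel_ge(record, i, thr) -> bool:
    """Velocity of sample i counts as >= threshold (no velocity, or a
    not-detected sample, counts as below)."""
    if not record.detected[i]:
        return False
    v = record.v[i]
    return (not math.isnan(v)) and v >= thr


def oracle_classify(record, thr, n, empty_window_passes=False):
    """Literal rule cascade: 0 = not detected, 1 = halting, 2 = moving."""
    N = record.n_samples
    states = []
    prev = "unknown"
    for i in range(N):
        cur = None
        # --- moving?
        start_window = list(range(i + 1, min(i + n, N - 1) + 1))
        if start_window:
            any_next_moving = any(_vel_ge(record, j, thr)
                                  for j in start_window)
        else:
            any_next_moving = empty_window_passes
        incl_window = list(range(i, min(i + n, N - 1) + 1))
        if prev != "moving" and _vel_ge(record, i, thr) and any_next_moving:
            cur = "moving"          # start moving
        elif prev == "moving" and any(_vel_ge(record, j, thr)
                                      for j in incl_window):
            cur = "moving"          # remain moving
        # --- else halting?
        elif prev != "halting" and record.detected[i]:
            cur = "halting"         # start halting
        elif prev == "halting" and any(record.detected[j]
                                       for j in incl_window):
            cur = "halting"         # remain halting
        else:
            cur = "not_detected"
        states.append(cur)
        prev = cur
    code = {"not_detected": 0, "halting": 1, "moving": 2}
    return [code[s] for s in states]
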