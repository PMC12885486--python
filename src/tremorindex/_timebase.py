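"""Shared sample/chunk timing arithmetic for gap-aware series."""

from __future__ import annotations


def chunk_table(
    start_epoch: float, n: int, fs: float, gaps: list[tuple[float, float]]
) -> list[tuple[float, int, int]]:
    """Contiguous sample runs as ``(chunk_start_epoch, i0, i1)`` triples.

    The first chunk starts at ``start_epoch``; chunk k > 0 starts at the end
    of gap k-1.  Chunk lengths are inferred from the gap start times, so gap
    boundaries must lie on (or within half a period of) the sample grid.
    """
    out: list[tuple[float, int, int]] = []
    t0 = start_epoch
    i0 = 0
    for (ga, gb) in gaps:
        m = int(round((ga - t0) * fs))
        out.append((t0, i0, i0 + m))
        i0 += m
        t0 = gb
    out.append((t0, i0, n))
    return [(t, a, b) for (t, a, b) in out if b > a]
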