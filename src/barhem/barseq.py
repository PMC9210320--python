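"""Bar-seq amplicon counting, restricted to the Tn-seq-validated catalog.

Barcodes are read out between two universal priming flanks; extraction
tolerates up to two mismatches per flank. Counting is catalog-restricted:
an extracted barcode is tallied only if it matches a Tn-seq-validated
barcode exactly — anything else (sequencing errors, clones never seen in
Tn-seq) is an orphan and is discarded, mirroring the rule that no barcode
seen only in Bar-seq enters the screen.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable

import numpy as np
import pandas as pd


def _find_with_mismatches(read: str, probe: str, max_mismatches: int) -> int:
    """Leftmost offset where ``probe`` matches ``read`` with <= m mismatches; -1 if none."""
    arr = np.frombuffer(read.encode(), dtype=np.uint8)
    p = np.frombuffer(probe.encode(), dtype=np.uint8)
    if arr.size < p.size:
        return -1
    windows = np.lib.stride_tricks.sliding_window_view(arr, p.size)
    dists = (windows != p).sum(axis=1)
    hits = np.flatnonzero(dists <= max_mismatches)
    return int(hits[0]) if hits.size else -1


def extract_barcode(read: str, upstream_flank: str, downstream_flank: str,
                    barcode_length: int = 20, max_flank_mismatches: int = 2
                    ) -> tuple[str | None, str]:
    """Pull the barcode out of one amplicon read.

    Locates the upstream flank (leftmost hit with Hamming distance <=
    ``max_flank_mismatches``), takes the next ``barcode_length`` bases, and
    verifies the downstream flank immediately after. Returns
    ``(barcode, "ok")`` or ``(None, reason)`` with reason in
    ``{"no_upstream_flank", "too_short", "no_downstream_flank"}``.
    """
    up = _find_with_mismatches(read, upstream_flank, max_flank_mismatches)
    if up < 0:
        return None, "no_upstream_flank"
    bc_start = up + len(upstream_flank)
    bc_end = bc_start + barcode_length
    down_end = bc_end + len(downstream_flank)
    if down_end > len(read):
        return None, "too_short"
    down = read[bc_end:down_end]
    mm = sum(a != b for a, b in zip(down, downstream_flank))
    if mm > max_flank_mismatches:
        return None, "no_downstream_flank"
    return read[bc_start:bc_end], "ok"


def count_barcodes(reads_by_sample: dict[str, Iterable[tuple[str, str]]],
                   catalog_barcodes: Iterable[str],
                   sample_sheet: pd.DataFrame,
                   upstream_flank: str, downstream_flank: str,
                   barcode_length: int = 20, max_flank_mismatches: int = 2
                   ) -> tuple[pd.DataFrame, dict]:
    """Tally catalog barcodes per sample from amplicon reads.

    ``reads_by_sample`` maps sample_id to ``(read_id, sequence)`` pairs;
    every sample must appear in ``sample_sheet``. Returns the barcode x
    sample count matrix (rows: all catalog barcodes, zero-filled) and a QC
    dict with per-sample accepted / rejected / orphan tallies satisfying
    accepted + rejected + orphan = total reads.
    """
    catalog = list(dict.fromkeys(catalog_barcodes))
    catalog_set = set(catalog)
    known_samples = set(sample_sheet["sample_id"])
    qc: dict[str, dict[str, int]] = {}
    columns: dict[str, Counter] = {}
    for sample, reads in reads_by_sample.items():
        if sample not in known_samples:
            raise ValueError(f"sample {sample!r} absent from sample sheet")
        tally: Counter = Counter()
        n_total = n_rejected = n_orphan = 0
        for _, seq in reads:
            n_total += 1
            bc, reason = extract_barcode(seq, upstream_flank, downstream_flank,
                                         barcode_length, max_flank_mismatches)
            if bc is None:
                n_rejected += 1
            elif bc in catalog_set:
                tally[bc] += 1
            else:
                n_orphan += 1
        columns[sample] = tally
        qc[sample] = {"total": n_total, "accepted": n_total - n_rejected - n_orphan,
                      "rejected": n_rejected, "orphan": n_orphan}
    counts = pd.DataFrame(
        {s: [columns[s].get(bc, 0) for bc in catalog] for s in columns},
        index=pd.Index(catalog, name="barcode"), dtype=int)
    return counts, qc
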