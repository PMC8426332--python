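"""Simulate a small cohort and call tumor-specific intron-retention events.

Builds a toy genome/annotation, draws per-sample region counts with planted
retained introns, applies the retention filters (counts > 10, 0.05 < TPM
ratio < 0.5), and subtracts the normal panel.
"""

import tempfile

from irneo import (
    SimConfig,
    build_normal_panel,
    call_sample_events,
    make_counts,
    make_reference,
    quantify_and_filter,
    read_count_table,
    subtract_normal,
)
from irneo.detection import region_lengths_of

with tempfile.TemporaryDirectory() as tmp:
    cfg = SimConfig(seed=7, n_genes=10, n_tumor_samples=6, n_normal_samples=3)
    ref = make_reference(cfg, tmp)
    counts = make_counts(cfg, ref, tmp)
    lengths = region_lengths_of(ref.introns)

    normals = read_count_table(counts.normal_counts)
    panel = build_normal_panel(
        [quantify_and_filter(c, lengths, s) for s, c in normals.items()]
    )
    print(f"normal panel: {len(panel)} events seen in >= 1 healthy sample")

    tumors = read_count_table(counts.tumor_counts)
    for sid, c in sorted(tumors.items()):
        events = call_sample_events(quantify_and_filter(c, lengths, sid))
        specific = subtract_normal(events, panel)
        print(f"{sid}: {len(events):2d} IR events, {len(specific):2d} tumor-specific")
# Per sample: events passing both retention filters, then the subset absent
# from every healthy control (the candidates that can yield neoantigens).
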