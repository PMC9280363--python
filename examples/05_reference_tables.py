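"""Summarise the packaged reference descriptor tables.

The package ships the published 57-family precursor descriptor table and
the 49-row known/predicted mature table for cluster bean (guar); this
recomputes the headline statistics from them.
"""

from guarmir.descriptors import (
    load_descriptor_table, load_mature_table, mature_length_mode, summarize,
)

rows = load_descriptor_table()
s = summarize(rows)
print(f"{len(rows)} precursor families")
print(f"|MFE|  : {s.mfe.minimum}..{s.mfe.maximum} kcal/mol, "
      f"mean {s.mfe.mean_rounded}")
print(f"|MFEI| : {s.mfei.minimum}..{s.mfei.maximum}, "
      f"mean {s.mfei.mean_rounded}")
print(f"AU%    : {s.au_pct.minimum}..{s.au_pct.maximum}")
print(f"GC%    : {s.gc_pct.minimum}..{s.gc_pct.maximum}")
print(f"length : {s.length.minimum:.0f}..{s.length.maximum:.0f} nt, "
      f"mean {s.length.mean_rounded:.0f}")

pairs = load_mature_table()
hist, mode = mature_length_mode([len(p.predicted_mature) for p in pairs])
print(f"\n{len(pairs)} predicted matures; length histogram {hist}")
print(f"modal mature length: {mode} nt — the canonical plant miRNA length")
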