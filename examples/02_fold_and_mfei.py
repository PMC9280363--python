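"""Fold a hairpin precursor and compute its descriptor statistics.

The MFEI — ((MFE/length) x 100) / GC% — separates pre-miRNA hairpins
from tRNA/rRNA/mRNA; values of magnitude >= 0.85 are a strong hairpin
signal, >= 0.6 the working acceptance threshold.
"""

from guarmir.descriptors import composition, mfei
from guarmir.fold import fold_nussinov
from guarmir.synth import make_hairpin

mature = "UGACAGAAGAAAGAGAGCAC"  # a real miR156 mature, 20 nt
precursor = make_hairpin(mature, loop_len=8, seed=1)
fold = fold_nussinov(precursor)

comp = composition(precursor)
index = mfei(fold.mfe, len(precursor), comp.gc_pct)

print(f"precursor ({len(precursor)} nt): {precursor}")
print(f"structure:            {fold.structure}")
print(f"MFE  = {fold.mfe:.1f} kcal/mol   (more negative = more stable)")
print(f"GC%  = {comp.gc_pct:.2f}   AU% = {comp.au_pct:.2f}")
print(f"MFEI = {index:.2f}   (|MFEI| >= 0.6 passes the hairpin filter)")
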