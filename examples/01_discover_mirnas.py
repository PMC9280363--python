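"""Discover miRNA hairpins in a synthetic EST set and score recovery.

Builds an EST collection with known hairpin precursors planted in half
of the sequences, runs the full pipeline (clean -> homology scan ->
fold/validate -> MFEI filter), and checks the result against the truth
manifest.
"""

from guarmir.descriptors import load_mature_table
from guarmir.pipeline import PipelineConfig, run_pipeline
from guarmir.seqio import SequenceRecord
from guarmir.synth import generate_est_set

# reference matures: real sequences from the packaged table
refs = [
    SequenceRecord(id=p.homolog_id, seq=p.known_mature, alphabet_hint="rna")
    for p in load_mature_table()[:12]
]

ests, manifest = generate_est_set(
    refs, n_ests=40, est_len=300, planted_fraction=0.5, mutation_rate=0.0,
    seed=17,
)
result = run_pipeline(ests, refs, config=PipelineConfig(n_bootstrap=20,
                                                        seed=17),
                      manifest=manifest)

for stage, n in result.stage_counts.items():
    print(f"{stage:>20}: {n}")
print(f"precursor recovery: {result.recovery['precursor_recovery_pct']:.0f}%")
print()
print("Per-stage survivor counts mirror a real EST-mining run; with no")
print("mutations every planted mature is rediscovered as a valid hairpin")
print("(100% recovery); the MFEI filter then collapses duplicate matures.")
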