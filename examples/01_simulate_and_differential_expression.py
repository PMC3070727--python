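"""Generate a synthetic two-species experiment and summarize differential expression.

The generator emulates a human lesional-vs-normal skin cohort (58 vs 64
samples) and a small mouse model experiment (3 vs 3), joined by a
many-to-many ortholog map covering ~61% of human transcripts.  A fraction
of transcripts carries planted log2 effects; the moderated t then ranks
them.  The printed counts are the sizes of the broad and strict human DE
selections and the mouse comparison-wise selection.
"""

from orthocorr import (
    SyntheticConfig,
    classify_de,
    differential_expression,
    generate_dataset,
    ortholog_coverage,
)

cfg = SyntheticConfig(seed=7)
ds = generate_dataset(cfg)
print(f"human matrix: {ds.human.shape[0]} transcripts x {ds.human.shape[1]} samples")
print(f"mouse matrix: {ds.mouse.shape[0]} transcripts x {ds.mouse.shape[1]} samples")
print(f"ortholog pairs: {ds.orthologs.n_pairs} "
      f"({ortholog_coverage(ds.orthologs, cfg.n_human_transcripts):.1f}% human coverage)")

human_de = differential_expression(ds.human)
mouse_de = differential_expression(ds.mouse)

for role, table in (("human_broad", human_de), ("human_strict", human_de),
                    ("mouse", mouse_de)):
    labels = classify_de(table, role)
    counts = labels.value_counts()
    print(f"{role:13s}: {counts.get('up', 0):4d} up, {counts.get('down', 0):4d} down, "
          f"{counts.get('ns', 0):5d} unchanged")

# the strict selection feeds the concordance tests; the broad one feeds
# term-level analyses and model clustering
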