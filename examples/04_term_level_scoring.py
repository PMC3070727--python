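"""Term-level correspondence: which annotated processes transfer across species.

Terms over-represented among human-increased transcripts are scored in the
mouse model by averaging the mouse ortholog fold changes and testing the
mean against zero (one-sample t).  The bracketed [x/y] counts are human
members and mapped mouse transcripts, mirroring how such tables are
usually printed.
"""

from orthocorr import (
    SyntheticConfig,
    classify_de,
    differential_expression,
    generate_dataset,
    overrepresentation_test,
    signature_set_score,
    term_correspondence,
)

ds = generate_dataset(SyntheticConfig(seed=31, rho=0.7, spikes={}))
human_de = differential_expression(ds.human)
mouse_de = differential_expression(ds.mouse)

labels = classify_de(human_de, "human_broad")
de_up = set(labels.index[labels == "up"])
enriched = overrepresentation_test(
    de_up, ds.terms, set(human_de.index), min_size=3
)
print(f"{len(enriched)} terms over-represented among {len(de_up)} "
      f"human-increased transcripts; top 5 by p:")
for term in enriched[:5]:
    members = set(ds.terms[term.term_id].members) & de_up
    tc = term_correspondence(term.term_id, members, ds.orthologs, mouse_de)
    star = "*" if tc.p < 0.05 else ("." if tc.marginal else " ")
    print(f"  {term.term_id} p={term.p:.2e} [{tc.n_human}/{tc.n_mouse}] "
          f"mean mouse log2fc = {tc.mean_mouse_log2fc:+.2f}{star} ({tc.call})")

# signature-set scoring: mean fold change of a directional response set
# (terms mix up- and down-regulated members, so score the up-subset the way
# a cytokine-response signature would be scored)
from orthocorr import GeneSet

up_members = sorted(set(ds.terms[enriched[0].term_id].members) & de_up)
gs = GeneSet(f"{enriched[0].term_id}_up", "up-regulated members", up_members)
score = signature_set_score(gs, human_de)
print(f"signature-set score of {gs.set_id} in the human table: "
      f"mean log2fc = {score.mean_log2fc:+.2f}, p = {score.p:.2e} "
      f"[{score.n_present}/{score.n_members} members present]")
# a '*' marks terms whose mouse orthologs shift significantly in the same
# direction as the human selection -- the cross-species concordant processes
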