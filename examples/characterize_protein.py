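"""Screen a published metallothionein sequence for MT-likeness.

Builds the 26-residue Neurospora crassa MT record, summarizes its
composition and applies the screening rule used in genome mining
(Cys fraction >= 15%, zero aromatic residues).
"""

from modmt import ProteinRecord, is_mt_like, summarize_composition

record = ProteinRecord("Ncrassa_MT", "MGDCGCSGASSCNCGSGCSCSNCGSK",
                       source="in_paper")
summary = summarize_composition(record)
verdict = is_mt_like(summary)

print(f"{record.id}: {summary.length} aa, {summary.cys_count} Cys "
      f"({100 * summary.cys_fraction:.1f}%), {summary.cys_in_cxc} Cys in CXC, "
      f"{summary.aromatic_count} aromatics")
print(f"average mass: {summary.average_mass_da:.2f} Da")
print(f"MT-like: {verdict.is_mt_like}")
for reason in verdict.reasons:
    print(f"  {reason}")

# A quarter of the residues are Cys, six of seven sit in CXC motifs and
# there are no aromatics: the classic sequence signature of a fungal
# Cu-thionein.
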