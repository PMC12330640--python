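"""Simulate a single-cell cohort with planted ITH programs and phenotypes.

Builds the default cohort: 16 cell-line samples of 300 cells each over
2000 genes, with 6 planted programs of 50 genes.  Two programs (0 and 1,
emulating the mutually exclusive hEMT and EpiSen states) are never active
in the same cell, and program 0 drives the per-sample metastatic
phenotypes.
"""

from ithkit import SyntheticSpec, generate_cohort, generate_phenotypes

spec = SyntheticSpec(seed=0)
matrix, truth = generate_cohort(spec)
phenotypes = generate_phenotypes(truth, spec)

print(f"cohort: {matrix.n_genes} genes x {matrix.n_cells} cells "
      f"({spec.n_samples} samples x {spec.cells_per_sample} cells)")
print(f"planted programs: {len(truth.program_gene_sets)} x "
      f"{spec.genes_per_program} genes")
n_coactive = sum(0 in s and 1 in s for s in truth.cell_program_labels)
print(f"cells active for both programs of the exclusive pair: {n_coactive}")
print("\nper-sample phenotypes (driven by program 0 activity):")
print(phenotypes.round(1).to_string(index=False))
# samples with a high fraction of program-0-active cells have high
# metastatic potential/penetrance; samples not expressing it sit near baseline
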