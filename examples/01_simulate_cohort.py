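"""Generate a synthetic radiogenomic cohort and inspect its design.

Builds a 28-patient cohort with the unbalanced zone availability of the
real study design (every patient has a cellular-tumor sample; necrosis and
edema zones only for subsets), one planted pathway-feature coupling, and
writes the plain-text fixture files.
"""

from radgex import CohortConfig, Coupling, generate_cohort, write_fixture

beta = Coupling.beta_for_signal_fraction(0.5)  # feature R2 vs latent = 0.5
config = CohortConfig(
    n_features=200, n_nzv_features=6, n_corr_blocks=4, block_size=5,
    n_genes=600, n_gene_sets=6, genes_per_set=25,
    planted_couplings=(Coupling("HALLMARK_SET_01", (20, 21), beta),),
    seed=42,
)
cohort = generate_cohort(config)

counts = cohort.radiomics.groupby("subcompartment").size()
complete = (cohort.radiomics.groupby("patient_id")["subcompartment"].nunique() == 3).sum()
print(f"radiomic rows per subcompartment: {counts.to_dict()}")
print(f"patients with all three subcompartments: {complete}")
print(f"expression matrix: {cohort.expression.values.shape[0]} genes x "
      f"{cohort.expression.values.shape[1]} zone samples")
print(f"planted couplings: {cohort.truth['couplings']}")

manifest = write_fixture(cohort, "scratch/example_cohort")
print("fixture files:", ", ".join(sorted(manifest)))
# ET/NET/ED counts of 28/15/7 give the 50-observation unbalanced design the
# downstream mixed models and patient-level averaging are built around.
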