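"""Curate raw screening results into CIAT/NCIAT training tables.

Runs the full reconciliation chain on a simulated campaign: Z-score flags
take precedence over percent-effect flags, conflicting calls resolve to
active, inconclusive-only records are dropped, and artefact (counter-
screen) outcomes turn primary actives into CIAT or NCIAT labels.
"""

from ciat_triage import GeneratorConfig, curate_campaign, simulate_campaign

config = GeneratorConfig(
    n_compounds=4000,
    technologies=("AlphaScreen", "FRET"),
    n_primary_assays=4,
    n_extra_primary_assays=8,
    seed=11,
)
campaign = simulate_campaign(config)
datasets = curate_campaign(campaign)

for tech, ds in datasets.items():
    print(ds.summary())
    multi = sum(len(a) > 1 for a in ds.table["active_assays"])
    print(f"  active in more than one assay: {multi} compounds "
          f"({100 * multi / len(ds):.0f} %)")

# Each line mirrors a training-set composition table: labeled compounds,
# interferers (CIATs) and clean actives (NCIATs) with the class prevalence.
# Compounds active in several assays are the ones a held-out assay will see
# again as "Set A"; single-assay compounds become the novel "Set B".
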