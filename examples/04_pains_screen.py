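"""Apply the 480-pattern PAINS substructure catalog.

PAINS alerts flag chemotypes associated with pan-assay interference.
They were derived from one bead-based luminescence screening platform, so
on curated counter-screen data they recover only a minority of true
technology interferers -- worth keeping in mind when using them as a
blanket triage filter.
"""

from ciat_triage import load_pains_catalog, match_pains

catalog = load_pains_catalog()
print(f"catalog: {len(catalog)} SMARTS patterns "
      f"(e.g. {catalog.names[0]}, {catalog.names[-1]})")

structures = {
    "para-quinone": "O=C1C=CC(=O)C=C1",
    "aryl quinone": "Cc1ccccc1C1=CC(=O)C=CC1=O",
    "catechol": "Oc1ccccc1O",
    "azobenzene": "c1ccc(N=Nc2ccccc2)cc1",
    "ibuprofen-like": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "plain ether": "CCOCC",
}
for name, smiles in structures.items():
    hits = match_pains(smiles, catalog)
    verdict = ", ".join(hits) if hits else "clean"
    print(f"  {name:15s} {verdict}")

# Quinones, catechols and azo dyes are canonical PAINS chemotypes; the two
# non-reactive comparison structures pass the filter untouched.
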