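"""Morphogenetic trait space: estimate traits for all six species, then PCA.

Each species contributes two noisily measured virtual plants; the pooled
individuals x traits matrix is standardized (traits carry mixed units) and
decomposed.  The leading components separate species by leaf size vs phytomer
production rate and by their organ-growth coordination.
"""

import pandas as pd

import legumorph as lm
from legumorph.synthetic import NoiseModel, SamplingSchedule, generate_observations

records = []
for i, species in enumerate(lm.packaged_species()):
    config = lm.get_species(species)
    dataset, _ = generate_observations(
        config, SamplingSchedule(horizon_days=80),
        NoiseModel(length_sd=0.05, stage_sd=0.2, area_sd=0.05, seed=10 + i),
        n_plants=2)
    traits, _ = lm.estimate_traits(dataset)
    records.append(traits.reset_index())

matrix = lm.assemble_trait_matrix(pd.concat(records, ignore_index=True))
result = lm.pca_traits(matrix.values)

print("variance explained per component:")
for name, frac in zip(result.loadings.columns, result.variance_fraction):
    print(f"  {name}: {frac:6.1%}")
print("\nPC1/PC2 loadings (which traits drive each axis of the morphospace):")
print(result.loadings[["PC1", "PC2"]].round(2).to_string())
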