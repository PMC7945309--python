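"""The packaged study design: populations, taxa and sample sizes.

The shipped table lists the 63 sampled populations of the European
*Cherleria* clade with their taxon assignment (the Albanian population of
*C. capillacea* kept as its own taxon), the number of individuals in the
final dataset, and whether the population represents its taxon in the
Taxon dataset.  It drives desk-scale fixtures and the taxon-level unit
check; per-individual rows are synthesised on demand.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_study_grouping", "expand_individuals", "STUDY_TAXA"]

STUDY_TAXA = (
    "baldaccii", "capillacea", "capillacea_albanian", "dirphya", "doerfleri",
    "garckeana", "langii", "laricifolia_laricifolia",
    "laricifolia_ophiolitica", "parnonia", "rupestris", "sedoides",
    "wettsteinii",
)


def load_study_grouping() -> pd.DataFrame:
    """Population-level grouping: population, taxon, n_individuals,
    taxon_representative."""
    with resources.files("gbsfoil.data").joinpath("study_grouping.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    df["taxon_representative"] = df["taxon_representative"].astype(bool)
    return df


def expand_individuals(grouping: pd.DataFrame | None = None) -> pd.DataFrame:
    """Individual-level grouping frame (individual, population, taxon),
    one synthetic individual id per sampled plant."""
    grouping = grouping if grouping is not None else load_study_grouping()
    rows = []
    for row in grouping.itertuples(index=False):
        for i in range(1, int(row.n_individuals) + 1):
            rows.append({"individual": f"{row.population}_i{i}",
                         "population": row.population, "taxon": row.taxon})
    return pd.DataFrame(rows)
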