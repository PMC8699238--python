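"""Bundled reference data.

The package ships the published 26-cluster x 2-condition contingency table of
the branded/unbranded brand-equity meta-analysis (26 k-means clusters of 1412
activation foci; 679 branded, 733 unbranded).  The raw foci behind it were
never deposited, but with cluster membership as the only feature the contrast
and classification stages are fully determined by these counts, so the table
serves both as a worked example and as a regression fixture.
"""

from importlib import resources

import pandas as pd

from .contrast import make_contingency


def load_brand_contingency() -> pd.DataFrame:
    """The published 26x2 cluster-by-condition count table.

    Returns
    -------
    pandas.DataFrame
        Index ``cl_0 ... cl_25``; columns ``label1`` (branded) and ``label0``
        (unbranded).  Column sums are 679 and 733 (1412 foci).
    """
    ref = resources.files("focimeta.data").joinpath("brand_contingency.tsv")
    with resources.as_file(ref) as path:
        raw = pd.read_csv(path, sep="\t")
    return make_contingency(
        raw["cluster_id"], raw["branded"].to_numpy(), raw["unbranded"].to_numpy()
    )
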