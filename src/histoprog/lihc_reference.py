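"""Published TCGA-LIHC cohort summary tables used as consistency inputs.

Published per-backbone summaries for the TCGA-LIHC cohort: the number of
image features univariately associated with overall survival (OS) and
disease-free survival (DFS) for each pretrained backbone and crop size, and
the cross-backbone overlap of the two discovered subgroups. These summaries
are treated as input data: the package's arithmetic (percentages, averages,
margins, totals) must reproduce them exactly.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "univariate_screen_table",
    "subgroup_overlap_table",
    "MEDIAN_IMAGE_WIDTH",
    "MEDIAN_IMAGE_HEIGHT",
    "N_TUMOR_SAMPLES",
    "N_NORMAL_SAMPLES",
]

#: Median level-3-equivalent slide raster, pixels.
MEDIAN_IMAGE_WIDTH = 5601.0
MEDIAN_IMAGE_HEIGHT = 2249.5

N_TUMOR_SAMPLES = 421
N_NORMAL_SAMPLES = 105

_SCREEN_ROWS = [
    # model, n_features, crop_size, significant OS, significant DFS
    ("VGG", 1408, 256, 272, 219),
    ("Inception", 2048, 256, 574, 294),
    ("ResNet", 2048, 256, 522, 385),
    ("VGG", 1408, 512, 300, 201),
    ("Inception", 2048, 512, 356, 290),
    ("ResNet", 2048, 512, 347, 390),
]

_OVERLAP_ROWS = [
    # inception group, vgg group, resnet group, sample count
    (1, 1, 1, 176),
    (1, 1, 2, 18),
    (1, 2, 1, 20),
    (1, 2, 2, 4),
    (2, 1, 1, 48),
    (2, 1, 2, 109),
    (2, 2, 1, 16),
    (2, 2, 2, 30),
]


def univariate_screen_table() -> pd.DataFrame:
    """Per-backbone counts of survival-associated features (published)."""
    return pd.DataFrame(
        _SCREEN_ROWS,
        columns=["model", "n_features", "crop_size", "significant_os", "significant_dfs"],
    )


def subgroup_overlap_table() -> pd.DataFrame:
    """Cross-backbone subgroup (1/2) overlap counts over tumor samples."""
    return pd.DataFrame(
        _OVERLAP_ROWS, columns=["inception", "vgg", "resnet", "count"]
    )
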