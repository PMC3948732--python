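"""Bundled reference tables.

Whole-ovary follicle counts from the eight-ovary sheep cortex study that
motivates this package: both ovaries of four young ewes were fully
sectioned, every sixth 5-µm section was analyzed, and primordial and
primary follicles with visible nuclei were counted on each section.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["whole_ovary_counts", "reference_variance_components"]

_WHOLE_OVARY_ROWS = [
    # (ewe, ovary, sections analyzed, primordial, primary)
    ("ewe1", "ov1", 657, 5624, 325),
    ("ewe1", "ov2", 669, 8572, 317),
    ("ewe2", "ov1", 632, 7746, 235),
    ("ewe2", "ov2", 567, 6808, 628),
    ("ewe3", "ov1", 301, 2409, 619),
    ("ewe3", "ov2", 360, 2369, 320),
    ("ewe4", "ov1", 378, 2345, 267),
    ("ewe4", "ov2", 288, 1285, 267),
]


def whole_ovary_counts() -> pd.DataFrame:
    """Per-ovary section and follicle counts of the reference study.

    3,852 analyzed sections in total; the primordial column sums to 37,158
    and the primary column to 2,978.
    """
    return pd.DataFrame(
        _WHOLE_OVARY_ROWS,
        columns=["ewe_id", "ovary_id", "sections_analyzed", "n_primordial", "n_primary"],
    )


def reference_variance_components() -> dict:
    """Fragment/section variance components fitted in the reference study.

    Log10-scale variances with standard errors; sections within a fragment
    carry ~90% of the total variance.
    """
    return {
        "sigma2_fragment": 0.116,
        "se_fragment": 0.037,
        "sigma2_section": 0.993,
        "se_section": 0.023,
    }
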