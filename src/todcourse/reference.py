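"""Published summary counts for the rice developmental time course.

The printed per-condition cycling summary of the field-grown rice
developmental study (27,648 array genes; nine leaf and two root diurnal
time courses): total genes, genes called not expressed, and genes called
rhythmic.  These counts are consumed as input data — e.g. to exercise the
mixed-denominator percentage convention of :func:`todcourse.cycling_detection.summarize_counts` —
never recomputed here (recomputation requires the original arrays).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["TABLE1_COUNTS", "summary_table"]

#: condition -> (total, not_expressed, rhythmic)
TABLE1_COUNTS = {
    "leaf_15d": (27648, 4735, 15615),
    "leaf_29d": (27648, 4893, 13068),
    "leaf_43d": (27648, 4713, 13317),
    "leaf_57d": (27648, 4945, 16909),
    "leaf_78d": (27648, 5180, 16995),
    "leaf_85d": (27648, 5213, 19848),
    "leaf_92d": (27648, 4552, 18234),
    "leaf_99d": (27648, 5676, 17650),
    "leaf_113d": (27648, 4701, 17593),
    "root_15d": (27648, 1637, 2359),
    "root_43d": (27648, 2265, 1216),
}


def summary_table() -> pd.DataFrame:
    """The published counts run through the summarizer convention."""
    from .cycling_detection import summarize_counts

    rows = {
        cond: summarize_counts(total, ne, rhythmic)
        for cond, (total, ne, rhythmic) in TABLE1_COUNTS.items()
    }
    return pd.DataFrame(rows).T
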