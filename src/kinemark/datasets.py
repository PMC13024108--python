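"""Bundled reference tables.

``load_cohort`` returns the demographic/clinical characteristics of the
14-patient post-arthroplasty validation cohort (9 THA, 5 TKA; bilateral
hip replacements listed as single rows): age in years, weight in kg,
height in m, surgery type, and months since surgery.
"""

from __future__ import annotations

import io

import pandas as pd

__all__ = ["load_cohort"]

_COHORT_CSV = """\
age_years,weight_kg,height_m,surgery_type,months_since_surgery
61,78,1.63,Left THA,60
50,94,1.72,Left THA,2
64,61.5,1.48,Right TKA,2
73,69.8,1.56,Left TKA,1
48,67,1.54,Left and Right THA,2
72,72,1.89,Right TKA,2
66,58,1.57,Left TKA,3
68,68,1.63,Left THA,1.5
77,68.3,1.37,Right TKA,3
50,74,1.58,Left and Right THA,12
63,47.3,1.42,Left THA,3
55,78.5,1.5,Left THA,6
46,90,1.72,Left and Right THA,1
53,55,1.57,Left THA,1.5
"""


def load_cohort() -> pd.DataFrame:
    """The 14-row validation-cohort table as a DataFrame."""
    return pd.read_csv(io.StringIO(_COHORT_CSV))
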