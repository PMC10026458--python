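"""Embedded benchmark tables for the nine-tube NiCl2/agarose CMR phantom.

These are the phantom's published calibration and quality-assurance
benchmark data, shipped with the package so that the recipe model, the
virtual phantom truth values and the QA arithmetic can all run without any
scanner data:

* :func:`calibration_table` — per-tube ingredient concentrations and the
  T1/T2 measured on a 1.4 T benchtop relaxometer (22 °C) and on 1.5 T / 3 T
  clinical systems by inversion-recovery gradient echo and single-echo spin
  echo.  Rows A–I are the nine internal tubes; the ``outer`` row is the
  HDPE-bead-loaded outer matrix fill (1.4 T values only).
* :func:`t2_comparison_table` — per-tube T2 from T2-prepared bSSFP mapping
  vs the long-TR spin-echo reference at both field strengths (baseline).
* :func:`longterm_table` — per-tube bSSFP T2 at baseline and at the
  12-month repeat scan, both field strengths.

All tables are returned as fresh :class:`pandas.DataFrame` objects indexed
by tube id.
"""

from __future__ import annotations

import io

import pandas as pd

TUBE_IDS = ["A", "B", "C", "D", "E", "F", "G", "H", "I"]

#: Corner positions of the 3x3 tube array (nearest the bottle edge).
CORNER_TUBES = ("A", "B", "F", "I")
#: Edge-midpoint and centre positions of the 3x3 array.
CENTRAL_TUBES = ("C", "D", "E", "G", "H")

# tube_id, agarose %w/v, NiCl2 mM, T1 @1.4/1.5/3 T (ms), T2 @1.4/1.5/3 T (ms)
_CALIBRATION_CSV = """\
tube_id,agarose_pct,ni_mM,t1_1p4T_ms,t1_1p5T_ms,t1_3T_ms,t2_1p4T_ms,t2_1p5T_ms,t2_3T_ms
A,1.261,3.139,821,803,807,40,35,34
B,0.969,2.511,978,982,988,50,43,41
C,0.773,2.639,1122,1073,1137,48,42,40
D,0.821,1.775,1083,1090,1130,71,60,59
E,0.649,1.791,1237,1225,1228,70,61,59
F,0.882,2.081,1030,1015,1019,60,52,50
G,0.594,1.562,1295,1287,1302,82,70,68
H,0.664,2.139,1221,1182,1217,60,52,51
I,2.840,2.502,440,435,445,47,41,40
outer,1.155,0.780,850,,,140,,
"""

# bSSFP T2 mapping vs spin-echo reference, per tube and field strength (ms)
_T2_COMPARISON_CSV = """\
tube_id,bssfp_1p5T_ms,se_1p5T_ms,bssfp_3T_ms,se_3T_ms
A,43,35,43,34
B,49,43,48,41
C,47,42,45,40
D,65,60,65,59
E,65,61,65,59
F,57,52,57,50
G,74,70,72,68
H,57,52,56,51
I,56,41,56,40
"""

# bSSFP T2 at baseline and 12-month repeat, per tube and field strength (ms)
_LONGTERM_CSV = """\
tube_id,baseline_1p5T_ms,repeat_1p5T_ms,baseline_3T_ms,repeat_3T_ms
A,43,43,43,43
B,49,49,48,49
C,47,47,45,45
D,65,66,65,65
E,65,65,65,65
F,57,57,57,57
G,74,73,72,71
H,57,57,56,56
I,56,57,56,57
"""


def _read(csv_text: str) -> pd.DataFrame:
    return pd.read_csv(io.StringIO(csv_text), index_col="tube_id")


def calibration_table() -> pd.DataFrame:
    """Tube recipes and measured T1/T2 (ms) at 1.4, 1.5 and 3 T."""
    return _read(_CALIBRATION_CSV)


def t2_comparison_table() -> pd.DataFrame:
    """Baseline bSSFP-mapping vs spin-echo-reference T2 per tube (ms)."""
    return _read(_T2_COMPARISON_CSV)


def longterm_table() -> pd.DataFrame:
    """Baseline vs 12-month bSSFP T2 per tube (ms)."""
    return _read(_LONGTERM_CSV)
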