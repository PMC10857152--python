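"""Published cohort description tables, reproduced verbatim as fixtures.

Two tables describe the 19-case phantom cohort the accuracy study was run
on: the demographic table (sex, age, pathology, lesion localization,
surgical position per case) and the per-case hologram-content table
(reference modality, which structures were segmented, and the fiducial
marker count).  They are shipped as in-memory CSV text and emitted by
:func:`write_fixture_tables` for the descriptive-statistics stage.

Note: the per-case marker column of the hologram table sums to 125 while
its printed "Overall" row (and the study's headline landmark count) says
124.  The tables are reproduced verbatim, discrepancy included; the
descriptive stage reports both numbers.
"""

from __future__ import annotations

import io
from pathlib import Path

import pandas as pd

__all__ = [
    "demographics_table",
    "hologram_table",
    "write_fixture_tables",
    "PRINTED_OVERALL_MARKERS",
]

#: Overall marker count as printed in the source table's summary row.
PRINTED_OVERALL_MARKERS = 124

_DEMOGRAPHICS_CSV = """\
case,sex,age,pathology,localization,position
01,M,49,Metastasis,Left temporal,supine
02,M,58,Diffused astrocytoma,Right temporal,supine
03,M,8,Cavernous malformation,Left frontal,supine
04,M,62,Meningioma,Left cerebellar,prone
05,M,41,Diffuse large B-cell lymphoma,Left occipital,prone
06,F,27,Meningioma,Left frontal,supine
07,M,51,Metastasis,Right occipital,prone
08,F,66,Metastasis,Bilateral occipital,prone
09,F,37,Aneurysm,Fourth ventricular,prone
10,F,73,Metastasis,Right parietal,left_lateral
11,F,54,Meningioma,Left parietal,left_lateral
12,M,79,Metastasis,Left occipital,right_lateral
13,F,41,High grade glioma,Left parietal,right_lateral
14,M,74,Metastasis,Right frontal and occipital,left_lateral
15,F,58,Metastasis,Left occipital,prone
16,M,84,Hematoma,Right frontal,supine
17,M,63,Hematoma,Right basal ganglia,supine
18,M,57,Hematoma,Right basal ganglia,supine
19,M,51,Hematoma,Left basal ganglia,supine
"""

# Hologram content per case: n_lesions counts "(2)" entries as two;
# boolean columns are 1 = segmented, 0 = not.
_HOLOGRAM_CSV = """\
case,reference_image,n_lesions,arteries,venous_sinus,ventricle,frontal_sinus,optic_radiation,pyramidal_tract,puncture_path,endoscopic_path,bone_flap,n_markers,scalp_quadrants
01,T1,1,1,1,1,0,1,0,0,0,0,7,1
02,T1,1,1,1,1,0,1,0,0,0,0,7,1
03,T1,1,1,1,1,0,0,0,0,0,0,7,1
04,T1,1,1,1,1,0,0,0,0,0,0,7,1
05,T1,1,1,1,1,0,1,0,0,0,0,7,1
06,T1,1,1,1,1,0,0,1,0,0,0,7,1
07,T1,1,1,1,1,0,0,0,0,0,0,7,1
08,T1,2,1,1,1,0,1,0,0,0,0,7,1
09,T1,1,1,1,1,0,0,1,0,0,0,6,1
10,T1,1,1,1,1,0,0,1,0,0,0,6,1
11,T1,1,1,1,1,0,0,1,0,0,0,6,1
12,T1,1,1,1,1,0,1,1,0,0,0,6,1
13,T1,1,1,1,1,0,0,1,0,0,0,6,1
14,T1,2,1,1,1,0,1,1,0,0,0,6,1
15,T1,1,1,1,1,0,1,0,0,0,0,6,1
16,CT,1,0,0,1,1,0,0,1,0,0,7,1
17,CT,1,0,0,1,1,0,0,1,1,1,6,1
18,CT,1,0,0,1,1,0,0,1,1,1,7,1
19,CT,1,0,0,1,0,0,0,1,1,1,7,1
"""


def demographics_table() -> pd.DataFrame:
    """The 19-case demographic table (sex, age, pathology, position)."""
    return pd.read_csv(io.StringIO(_DEMOGRAPHICS_CSV), dtype={"case": str})


def hologram_table() -> pd.DataFrame:
    """The per-case hologram-content table (lesion and marker counts)."""
    return pd.read_csv(io.StringIO(_HOLOGRAM_CSV), dtype={"case": str})


def write_fixture_tables(outdir: str | Path) -> dict[str, Path]:
    """Emit both cohort tables as CSV files; re-emission is byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "demographics": outdir / "cohort_demographics.csv",
        "holograms": outdir / "cohort_holograms.csv",
    }
    paths["demographics"].write_text(_DEMOGRAPHICS_CSV)
    paths["holograms"].write_text(_HOLOGRAM_CSV)
    return paths
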