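"""Published study tables bundled as in-memory fixtures.

``f2_segregation_counts`` transcribes the printed per-marker a/h/b counts of
the 877-individual TSH516 selfing progeny across the chromosome-1 and
chromosome-4 fine-mapping regions.  The published per-marker "total" column
is redundant (it equals a+h+b for every marker except one transcription
inconsistency) and is therefore recomputed.

``f2_marker_table`` expands the counts into a pseudo-individual
:class:`~cacaosi.segregation_scan.MarkerTable` suitable for count-level
analyses (segregation tests, absent-class runs, region delimiting); the
expansion carries no linkage information between markers.

``reference_ssr_genotypes`` holds the reference variety SSR genotypes at the
three diagnostic markers (Amelonado Mat1-6, Criollo B97-61, Scavina 6).
"""

from __future__ import annotations

import pandas as pd

from .segregation_scan import MarkerTable

__all__ = ["f2_segregation_counts", "f2_marker_table", "reference_ssr_genotypes"]

# marker, chromosome, position (bp), n_a, n_h, n_b
_F2_ROWS = [
    ("mSI_26", "CH1", 3_377_732, 5, 228, 118),
    ("mSI_88", "CH1", 3_499_444, 5, 224, 111),
    ("mSI_89", "CH1", 3_525_756, 5, 233, 114),
    ("mSI_32", "CH1", 3_649_333, 4, 236, 120),
    ("mTcCIR15", "CH1", 3_711_664, 4, 227, 117),
    ("mSI_73", "CH1", 3_790_637, 4, 291, 138),
    ("mSI_101", "CH1", 3_935_902, 3, 243, 119),
    ("mSI_102", "CH1", 3_966_163, 2, 249, 119),
    ("mSI_140", "CH1", 3_988_656, 2, 217, 125),
    ("mSI_141", "CH1", 4_010_921, 2, 308, 138),
    ("mSI_103", "CH1", 4_021_267, 3, 387, 228),
    ("mSI_366", "CH1", 4_053_385, 0, 508, 253),
    ("mSI_367", "CH1", 4_054_418, 0, 366, 216),
    ("mSI_369", "CH1", 4_057_532, 0, 419, 221),
    ("mSI_440", "CH1", 4_066_036, 0, 476, 253),
    ("mSI_370", "CH1", 4_070_474, 0, 466, 266),
    ("mSI_372", "CH1", 4_073_585, 0, 297, 170),
    ("mSI_375", "CH1", 4_091_577, 2, 429, 228),
    ("mSI_107", "CH1", 4_130_575, 4, 374, 212),
    ("mTcCIR356", "CH1", 4_149_062, 6, 232, 118),
    ("mSI_112", "CH1", 4_233_257, 6, 339, 163),
    ("mSI_113", "CH1", 4_252_975, 6, 284, 172),
    ("mSI_462", "CH4", 1_414, 222, 425, 2),
    ("mSI_466", "CH4", 4_737, 191, 385, 0),
    ("mSI_474", "CH4", 10_127, 198, 380, 0),
    ("mSI_7", "CH4", 20_673, 259, 488, 0),
    ("mSI_34", "CH4", 28_166, 238, 487, 0),
    ("mSI_8", "CH4", 28_166, 142, 270, 0),
    ("mTcCir312", "CH4", 32_259, 277, 516, 0),
    ("mSI_35", "CH4", 33_618, 183, 348, 0),
    ("mSI_2", "CH4", 43_494, 191, 335, 0),
    ("mSI_542", "CH4", 63_388, 33, 68, 0),
    ("mSI_303", "CH4", 119_995, 299, 578, 0),
    ("mSI_458", "CH4", 136_890, 208, 399, 0),
    ("mSI_460", "CH4", 139_590, 198, 406, 0),
    ("mSI_308", "CH4", 139_780, 211, 408, 0),
    ("mSI_309", "CH4", 141_679, 205, 411, 0),
    ("mSI_310", "CH4", 142_517, 193, 383, 0),
    ("mSI_315", "CH4", 233_706, 301, 563, 0),
    ("mSI_402", "CH4", 246_098, 259, 506, 0),
    ("mSI_535", "CH4", 252_815, 110, 232, 0),
    ("mSI_411", "CH4", 258_684, 125, 242, 1),
    ("mS_413", "CH4", 270_916, 118, 253, 1),
    ("mSI_39", "CH4", 278_179, 277, 421, 1),
    ("mSI_42", "CH4", 343_424, 109, 233, 2),
    ("mSI_46", "CH4", 428_250, 119, 230, 2),
    ("mSI_54", "CH4", 751_986, 55, 127, 4),
    ("mSI_294", "CH4", 1_686_245, 109, 248, 16),
]


def f2_segregation_counts() -> pd.DataFrame:
    """Per-marker genotype-class counts of the selfed-F2 fine-mapping progeny."""
    df = pd.DataFrame(
        _F2_ROWS, columns=["marker", "chromosome", "position", "n_a", "n_h", "n_b"]
    )
    df["total"] = df[["n_a", "n_h", "n_b"]].sum(axis=1)
    return df


def f2_marker_table() -> MarkerTable:
    """The F2 counts expanded into a pseudo-individual marker table."""
    return MarkerTable.from_counts(f2_segregation_counts().set_index("marker"))


def reference_ssr_genotypes() -> dict[str, dict[str, tuple[int, int]]]:
    """Reference variety genotypes at the three diagnostic SSR markers."""
    return {
        "Amelonado": {
            "mSI_460": (161, 161),
            "mSI_103": (223, 223),
            "mSI_107": (245, 245),
        },
        "Criollo": {
            "mSI_460": (134, 134),
            "mSI_103": (228, 228),
            "mSI_107": (239, 239),
        },
        "Scavina6": {
            "mSI_460": (140, 149),
            "mSI_103": (225, 225),
            "mSI_107": (241, 243),
        },
    }
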