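import numpy as np
import pandas as pd
import pytest

from cacaosi.datasets import f2_marker_table
from cacaosi.diagnostic_screen import PhenotypeTable, SSRGenotypeTable
from cacaosi.si_model import (
    CrossSpec,
    DiploidGenotype,
    GameticFusionRule,
    SAllele,
    SIModel,
    ZygoticEliminationRule,
)


@pytest.fixture(scope="session")
def f2_table():
    """Pseudo-individual expansion of the published selfed-F2 marker counts."""
    return f2_marker_table()


@pytest.fixture
def sf():
    return SAllele("Sf", activity="amorphous", dominance_rank=2)


@pytest.fixture
def s_sca():
    return SAllele("S_sca", activity="active", dominance_rank=1)


@pytest.fixture
def tsh516_selfing(sf, s_sca):
    """TSH516 selfing at the chromosome-4 locus: Sf (Amelonado) / S_sca."""
    geno = DiploidGenotype("CH4", (sf, s_sca))
    cross = CrossSpec.selfing({"CH4": geno}, n_offspring=877, baseline_abortion=0.0)
    model = SIModel(gametic_rules={"CH4": GameticFusionRule()})
    return cross, model


@pytest.fixture
def br59_selfing():
    """BR59 selfing at the chromosome-1 locus: Amelonado 223 / Scavina-6 225.

    The Scavina-6 allele activates pre-fusion elimination of the
    Amelonado-homozygous zygote.
    """
    a223 = SAllele("A223")
    a225 = SAllele("A225")
    geno = DiploidGenotype("CH1", (a223, a225))
    cross = CrossSpec.selfing({"CH1": geno}, n_offspring=109, baseline_abortion=0.0)
    model = SIModel(
        zygotic_rules={
            "CH1": ZygoticEliminationRule(frozenset({("A225", "A223")}))
        }
    )
    return cross, model


@pytest.fixture
def toy_ssr_population():
    """Hand-built 10-tree SSR table with two markers and a clean SC predictor.

    Genotype 161/161 at M1 is carried by the four SC trees only.
    """
    rows = {
        f"t{i}": g
        for i, g in enumerate(
            [
                {"M1": (161, 161), "M2": (200, 204)},
                {"M1": (161, 161), "M2": (200, 200)},
                {"M1": (161, 161), "M2": (204, 204)},
                {"M1": (161, 161), "M2": (200, 204)},
                {"M1": (149, 161), "M2": (200, 204)},
                {"M1": (149, 161), "M2": (200, 200)},
                {"M1": (149, 149), "M2": (204, 204)},
                {"M1": (149, 149), "M2": (200, 204)},
                {"M1": (149, 161), "M2": (200, 200)},
                {"M1": (149, 149), "M2": (204, 204)},
            ]
        )
    }
    ssr = SSRGenotypeTable(pd.DataFrame.from_dict(rows, orient="index"))
    sc = pd.Series([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], index=list(rows))
    phen = PhenotypeTable(pd.DataFrame({"sc_status": sc}))
    return ssr, phen
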