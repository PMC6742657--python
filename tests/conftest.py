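import logging

import numpy as np
import pandas as pd
import pytest

from mechanoprot.ingest import ExperimentDesign, PeptideTable, default_registry

logging.getLogger("mechanoprot").setLevel(logging.ERROR)


@pytest.fixture
def two_sample_design() -> ExperimentDesign:
    return ExperimentDesign(
        pd.DataFrame(
            {
                "sample_id": ["ctrl_d1", "strain_d1"],
                "group": ["control", "strain"],
                "donor": ["d1", "d1"],
            }
        ),
        reference_group="control",
    )


def make_table(rows: list[dict], sample_ids: list[str]) -> PeptideTable:
    """Build a PeptideTable directly from row dicts (missing samples -> NaN)."""
    records = []
    for r in rows:
        rec = {
            "peptide_id": r["peptide_id"],
            "sequence": r.get("sequence", "ACDEFGHIK"),
            "modifications": r.get("modifications", ""),
            "accession": r.get("accession", "P1"),
            "unique": r.get("unique", True),
            "score": r.get("score", 30.0),
        }
        for s in sample_ids:
            rec[s] = r.get(s, np.nan)
        records.append(rec)
    return PeptideTable(pd.DataFrame(records), list(sample_ids), default_registry())


@pytest.fixture
def peptide_csv(tmp_path):
    """A small canonical peptide CSV on disk (3 rows, 2 samples)."""
    path = tmp_path / "peptides.csv"
    path.write_text(
        "peptide_id,sequence,modifications,accession,unique,score,ctrl_d1,strain_d1\n"
        "p1,VSSR,2:phospho,P1,True,30.0,1000.0,2000.0\n"
        "p2,ACDEFGHIK,,P1,True,25.0,1500.0,\n"
        "p3,LMNPQR,,P2,False,10.0,800.0,900.0\n"
    )
    return path
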