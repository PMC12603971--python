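"""Shared study definition for the numbered analysis scripts.

Two synthetic probes emulate the headline biological contrast: an
alkyl-ether-like lipid with fast non-vesicular PM->ER exchange ("ePC") and
a plasmalogen-like lipid whose PM->ER rate is half as large ("pPC"), all
other rates equal.  The chase-time grid and replication mirror a typical
pulse-chase imaging experiment.
"""

from pathlib import Path

import lipidflux as lf

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
RESULTS = ROOT / "results"

TIMES = (4.0, 10.0, 20.0, 30.0, 60.0, 120.0)
N_FIELDS_PER_TIME = 6
SEED = 20260926 % (2**31)

PROBES = {
    # k_pm_endo, k_endo_golgi, k_golgi_er, k_pm_er, k_er_pm  (1/min)
    "ePC": lf.KineticParams(0.008, 0.05, 0.05, 0.06, 0.02),
    "pPC": lf.KineticParams(0.008, 0.05, 0.05, 0.03, 0.02),
}


def dataset_dir(probe: str) -> Path:
    return SCRATCH / f"dataset_{probe}"
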