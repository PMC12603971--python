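"""Simulate pulse-chase imaging for the two synthetic probes.

Generates 6 fields of view per chase time (4-120 min) per probe, with the
lipid channel following each probe's ground-truth transport kinetics, and
writes the TIFF fields, probability masks and ground-truth fraction tables
under scratch/ (raw image data are intermediate artifacts; every number the
analysis reports is derived again by the later scripts).
"""

import dataclasses

import numpy as np

import lipidflux as lf
from common import N_FIELDS_PER_TIME, PROBES, SEED, TIMES, dataset_dir
from lipidflux import io as lio


def main() -> None:
    for i, (probe, truth) in enumerate(sorted(PROBES.items())):
        seed = int(np.random.SeedSequence([SEED, i]).generate_state(1)[0] % 2**31)
        scene = dataclasses.replace(lf.SceneConfig(), seed=seed)
        ds = lf.generate_dataset(
            scene, truth, TIMES, N_FIELDS_PER_TIME, probe_id=probe, n_no_uv=2
        )
        out = lio.write_dataset(ds, dataset_dir(probe))
        pm_final = ds.truth_series.fractions[-1, 0]
        print(
            f"{probe}: wrote {len(ds)} fields ({N_FIELDS_PER_TIME}/timepoint "
            f"+ 2 no-UV controls) to {out}; true PM fraction decays "
            f"1.00 -> {pm_final:.2f} over {TIMES[-1]:.0f} min"
        )


if __name__ == "__main__":
    main()
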