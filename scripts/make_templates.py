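"""Generate the packaged mean wall-spiral templates.

The templates are plateau-exponential spirals sampled every 22.5 deg
from 0 to 990 deg whose reference A/B equal the corrosion-cast
population means.  The shape parameters (decay constant tau, shape
exponent q, per wall) were calibrated once so that the mean-anatomy
insertion model reproduces the three published clinical EID/IA anchors
of the perimodiolar arrays; they are frozen here and the emitted CSV +
JSON files under src/modiolus/data/ are the package's versioned
templates.

Run from the repository root:  python scripts/make_templates.py
"""

from pathlib import Path

from modiolus.spiral import parametric_template, save_template

VERSION = "mean-v1"

# corrosion-cast population means (mm)
A_LAT, B_LAT, A_MOD, B_MOD = 9.24, 6.80, 5.46, 3.17

# frozen shape calibration (degrees; dimensionless exponents)
TAU_MODIOLAR = 101.0
Q_MODIOLAR = 1.0
TAU_LATERAL = 160.0
Q_LATERAL = 1.0


def main() -> None:
    out = Path(__file__).resolve().parents[1] / "src" / "modiolus" / "data"
    out.mkdir(parents=True, exist_ok=True)
    modiolar = parametric_template(
        "modiolar", A_MOD, B_MOD, TAU_MODIOLAR, Q_MODIOLAR, version=VERSION
    )
    lateral = parametric_template(
        "lateral", A_LAT, B_LAT, TAU_LATERAL, Q_LATERAL, version=VERSION
    )
    save_template(modiolar, out / "modiolar_mean.csv")
    save_template(lateral, out / "lateral_mean.csv")
    print(f"wrote templates ({VERSION}) to {out}")


if __name__ == "__main__":
    main()
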