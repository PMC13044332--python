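"""Build-time fit of the whole-body silhouette correction polynomial.

Computes, at each integer zenith angle 0-90 deg, the ratio of the empirical
standing-human projected area (rescaled to the default body's surface area)
to the geometric whole-body silhouette of the default assembled body, and
least-squares fits an 8th-order polynomial in normalised zenith (z/90).
Writes the coefficients (highest degree first, numpy polyfit convention) to
``src/partitherm/data/silhouette_correction.json``.

Run from the repository root:  python scripts/fit_silhouette_correction.py
"""

import json
from pathlib import Path

import numpy as np

from partitherm.anthropometry import (
    DEFAULT_PART_SPECS,
    _UW_REFERENCE_AREA,
    assemble_body,
    dubois_area,
    silhouette_area,
    underwood_ward_projected_area,
)

DEFAULT_MASS = 70.0  # kg
DEFAULT_HEIGHT = 1.75  # m


def main() -> None:
    area = dubois_area(DEFAULT_MASS, DEFAULT_HEIGHT)
    parts = assemble_body(DEFAULT_MASS, area, DEFAULT_HEIGHT, DEFAULT_PART_SPECS)
    zeniths = np.arange(91.0)
    ratios = []
    for z in zeniths:
        geom = sum(p.count * silhouette_area(p, float(z)) for p in parts)
        emp = underwood_ward_projected_area(float(z)) * area / _UW_REFERENCE_AREA
        ratios.append(emp / geom)
    coeffs = np.polyfit(zeniths / 90.0, np.array(ratios), 8)
    out = Path(__file__).resolve().parents[1] / "src" / "partitherm" / "data" / "silhouette_correction.json"
    payload = {
        "version": 1,
        "description": (
            "8th-order polynomial in normalised zenith (z/90), highest degree "
            "first, fitted to the ratio of the empirical standing-human "
            "projected area to the geometric whole-body silhouette of the "
            "default body at 91 integer zenith angles."
        ),
        "default_body": {"mass_kg": DEFAULT_MASS, "height_m": DEFAULT_HEIGHT, "area_m2": area},
        "coefficients": [float(c) for c in coeffs],
    }
    out.write_text(json.dumps(payload, indent=1))
    fitted = np.polyval(coeffs, zeniths / 90.0)
    resid = float(np.max(np.abs(fitted - np.array(ratios))))
    print(f"wrote {out}")
    print(f"ratio range [{min(ratios):.3f}, {max(ratios):.3f}], max fit residual {resid:.4f}")


if __name__ == "__main__":
    main()
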