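"""Versioned table of the model constants, overridable from a key=value file.

The published relations this package implements are parameterised by eight
numbers; they live here in one place so an override file can swap any of
them without touching code:

====================  ==========================  =========================
key                   meaning                     default
====================  ==========================  =========================
adag_slope            eAG per HbA1c percent       28.7 mg/dl per %
adag_intercept        eAG at HbA1c = 0            -46.7 mg/dl
linear_slope          HbA1c percent per eAG       0.0296 % per mg/dl
linear_intercept      HbA1c at zero glucose       2.419 %
kinetic_k             glycation rate constant     1.296e-9 l/(mmol*s)
lifespan_days         erythrocyte life span       120 days
kinetic_scale         kinetic-model span          91.5 %
kinetic_offset        kinetic-model baseline      2.15 %
====================  ==========================  =========================

plus the unit-conversion constant ``glucose_molar_mass`` (180.156 g/mol,
so 1 mmol/l = 18.0156 mg/dl).
"""

from __future__ import annotations

from pathlib import Path

CONSTANTS_VERSION = "1.0"

DEFAULTS: dict[str, float] = {
    "adag_slope": 28.7,
    "adag_intercept": -46.7,
    "linear_slope": 0.0296,
    "linear_intercept": 2.419,
    "kinetic_k": 1.296e-9,
    "lifespan_days": 120.0,
    "kinetic_scale": 91.5,
    "kinetic_offset": 2.15,
    "glucose_molar_mass": 180.156,
}


def load_constants(path: str | Path | None = None) -> dict[str, float]:
    """Return the constants table, optionally overridden from a plain-text
    ``key = value`` file (``#`` starts a comment; blank lines ignored).

    Unknown keys raise ``KeyError`` so typos do not silently do nothing.
    """
    table = dict(DEFAULTS)
    if path is None:
        return table
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key = key.strip()
        if key not in table:
            raise KeyError(f"{path}:{lineno}: unknown constant {key!r}")
        table[key] = float(value.strip())
    return table
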