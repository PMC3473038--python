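"""Nearest-neighbor thermodynamic model (Turner-style loop energies).

The bundled ``turner-min`` parameter set provides helix stacking energies for
all Watson-Crick and GU contexts, length-dependent hairpin/bulge/internal-loop
initiations with Jacobson-Stockmayer extrapolation beyond the tabulated range,
a capped linear asymmetry penalty for internal loops, and an affine multiloop
model ``a + b*(branches) + c*(unpaired)``.  Dangles, coaxial stacking and
special small-loop tables are deliberately out of scope.

Energies are free energies in kcal/mol at the model temperature; disallowed
configurations return ``+inf`` so they vanish from Boltzmann sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources

from .structures import ALLOWED_PAIRS

#: Universal gas constant, kcal/(mol*K).
R_GAS = 0.0019872

INF = math.inf


@dataclass(frozen=True)
class EnergyParams:
    """A complete nearest-neighbor parameter set."""

    stack: dict[tuple[str, str], float]
    hairpin_init: dict[int, float]  # keyed by loop length, contiguous from theta
    bulge_init: dict[int, float]
    internal_init: dict[int, float]
    asym_coeff: float
    asym_max: float
    ml_a: float  # multiloop closing
    ml_b: float  # per branch
    ml_c: float  # per unpaired base
    theta: int
    temperature: float
    max_loop: int
    js_coeff: float  # Jacobson-Stockmayer prefactor (dimensionless, x RT)
    name: str = "turner-min"

    @property
    def RT(self) -> float:
        return R_GAS * self.temperature

    def with_temperature(self, temperature: float) -> "EnergyParams":
        """Same free-energy tables evaluated at a different temperature.

        Only RT (and hence Boltzmann factors and extrapolation terms) change;
        enthalpy-based rescaling of the tables themselves is out of scope.
        """
        return replace(self, temperature=temperature)


def _validate(params: EnergyParams) -> None:
    for p1 in sorted(ALLOWED_PAIRS):
        for p2 in sorted(ALLOWED_PAIRS):
            if (p1, p2) not in params.stack:
                raise ValueError(f"parameter set incomplete: missing stack {p1}/{p2}")
            sym = params.stack[(p2[::-1], p1[::-1])]
            if abs(sym - params.stack[(p1, p2)]) > 1e-9:
                raise ValueError(f"stack table breaks rotational symmetry at {p1}/{p2}")
    for table, start, label in (
        (params.hairpin_init, params.theta, "hairpin"),
        (params.bulge_init, 1, "bulge"),
        (params.internal_init, 2, "internal"),
    ):
        if not table:
            raise ValueError(f"parameter set incomplete: empty {label} table")
        for u in range(start, max(table) + 1):
            if u not in table:
                raise ValueError(f"parameter set incomplete: {label} length {u} missing")
    if params.theta < 1:
        raise ValueError("theta must be >= 1")


def load_params(source: str = "turner-min", temperature: float | None = None) -> EnergyParams:
    """Load a parameter set from a built-in name or a file path.

    The plain-text format is sectioned (``[stack]``, ``[hairpin]``, ...); see
    the bundled ``data/turner_min.txt`` for the reference file.
    """
    if source == "turner-min":
        text = (
            resources.files("shapefold.data").joinpath("turner_min.txt").read_text()
        )
    else:
        with open(source) as fh:
            text = fh.read()
    sections: dict[str, list[list[str]]] = {}
    current: str | None = None
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if line.startswith("[") and line.endswith("]"):
            current = line[1:-1]
            sections[current] = []
            continue
        if current is None:
            raise ValueError(f"{source}: line {ln}: data before any section header")
        sections[current].append(line.split())
    try:
        general = dict((k, float(v)) for k, v in sections["general"])
        stack = {
            (p1, p2): float(e) for p1, p2, e in sections["stack"]
        }
        hairpin = {int(u): float(e) for u, e in sections["hairpin"]}
        bulge = {int(u): float(e) for u, e in sections["bulge"]}
        internal = {int(u): float(e) for u, e in sections["internal"]}
        ml = dict(sections["multiloop"])
        asym = dict(sections["asymmetry"])
    except KeyError as exc:
        raise ValueError(f"{source}: missing section {exc}") from exc
    params = EnergyParams(
        stack=stack,
        hairpin_init=hairpin,
        bulge_init=bulge,
        internal_init=internal,
        asym_coeff=float(asym["coeff"]),
        asym_max=float(asym["max"]),
        ml_a=float(ml["a"]),
        ml_b=float(ml["b"]),
        ml_c=float(ml["c"]),
        theta=int(general.get("theta", 3)),
        temperature=temperature if temperature is not None else general["temperature"],
        max_loop=int(general.get("max_loop", 30)),
        js_coeff=general.get("js_coeff", 1.75),
        name=source,
    )
    _validate(params)
    return params


def _extrapolate(table: dict[int, float], u: int, params: EnergyParams) -> float:
    """Tabulated initiation, or Jacobson-Stockmayer beyond the table."""
    umax = max(table)
    if u <= umax:
        return table[u]
    return table[umax] + params.js_coeff * params.RT * math.log(u / umax)


def stack_energy(seq: str, i: int, j: int, k: int, l: int, params: EnergyParams) -> float:
    """Stacking energy of outer pair (i,j) on inner pair (k,l)."""
    outer = seq[i] + seq[j]
    inner = seq[k] + seq[l]
    if outer not in ALLOWED_PAIRS or inner not in ALLOWED_PAIRS:
        return INF
    return params.stack[(outer, inner)]


def hairpin_energy(seq: str, i: int, j: int, params: EnergyParams) -> float:
    """Free energy of the hairpin loop closed by pair (i, j); 0-based."""
    if seq[i] + seq[j] not in ALLOWED_PAIRS:
        return INF
    u = j - i - 1
    if u < params.theta:
        return INF
    return _extrapolate(params.hairpin_init, u, params)


def internal_energy(
    seq: str, i: int, j: int, k: int, l: int, params: EnergyParams
) -> float:
    """Free energy of the two-pair loop (i,j)/(k,l): stack, bulge or internal.

    Requires ``i < k < l < j``.  Size-1 bulges keep the helix stack
    (initiation(1) plus the stacking energy of the closing pairs); larger
    bulges and proper internal loops use initiation by size, the latter with
    a capped linear asymmetry penalty.  Loops whose total unpaired size
    exceeds ``max_loop`` are forbidden.
    """
    if not (i < k < l < j):
        raise ValueError("internal loop requires i < k < l < j")
    if seq[i] + seq[j] not in ALLOWED_PAIRS or seq[k] + seq[l] not in ALLOWED_PAIRS:
        return INF
    n1 = k - i - 1
    n2 = j - l - 1
    size = n1 + n2
    if size > params.max_loop:
        return INF
    if size == 0:
        return params.stack[(seq[i] + seq[j], seq[k] + seq[l])]
    if n1 == 0 or n2 == 0:  # bulge
        e = _extrapolate(params.bulge_init, size, params)
        if size == 1:
            e += params.stack[(seq[i] + seq[j], seq[k] + seq[l])]
        return e
    e = _extrapolate(params.internal_init, size, params)
    e += min(params.asym_max, params.asym_coeff * abs(n1 - n2))
    return e


def multiloop_energy(branches: int, unpaired: int, params: EnergyParams) -> float:
    """Affine multiloop energy ``a + b*branches + c*unpaired``.

    ``branches`` counts all helices incident to the loop including the
    closing pair.
    """
    return params.ml_a + params.ml_b * branches + params.ml_c * unpaired
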