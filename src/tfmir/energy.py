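"""Nearest-neighbor energy parameters for intermolecular RNA:RNA duplexes.

A duplex structure is scored as one initiation penalty plus, for every two
consecutive base pairs, either a stacking free energy (when the pairs are
adjacent on both strands) or an affine bulge/internal-loop penalty for the
unpaired stretch between them.  Parameters live in a plain-text TSV; the
shipped default uses published Turner-style Watson-Crick stacking values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

__all__ = ["EnergyParams", "WC_PAIRS", "WOBBLE_PAIRS", "load_params", "toy_params", "default_params"]

WC_PAIRS = frozenset({"AU", "UA", "CG", "GC"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})


def _rev(pair: str) -> str:
    return pair[1] + pair[0]


@dataclass(frozen=True)
class EnergyParams:
    """Stacking table plus loop penalties (kcal/mol) and pairing rules.

    ``stack`` maps (5'-side pair, 3'-side pair) -> free energy, each pair
    written top-strand base then bottom-strand base.  ``max_loop`` caps the
    unpaired stretch allowed on either strand between consecutive pairs.
    """

    stack: dict[tuple[str, str], float]
    init_penalty: float = 0.0
    bulge_open: float = 0.0
    bulge_extend: float = 0.0
    internal_open: float = 0.0
    internal_extend: float = 0.0
    allow_gu: bool = True
    max_loop: int = 10

    def __post_init__(self) -> None:
        if self.max_loop < 0:
            raise ValueError("max_loop must be >= 0")
        for pen in (
            self.init_penalty,
            self.bulge_open,
            self.bulge_extend,
            self.internal_open,
            self.internal_extend,
        ):
            if pen < 0:
                raise ValueError("penalties must be >= 0")
        # fill symmetric partners: stack(P,Q) == stack(rev Q, rev P)
        expanded = dict(self.stack)
        for (p, q), e in list(expanded.items()):
            mirror = (_rev(q), _rev(p))
            expanded.setdefault(mirror, e)
        object.__setattr__(self, "stack", expanded)

    @property
    def pairs(self) -> frozenset[str]:
        return WC_PAIRS | WOBBLE_PAIRS if self.allow_gu else WC_PAIRS

    def can_pair(self, top: str, bottom: str) -> bool:
        return top + bottom in self.pairs

    def stack_energy(self, pair5: str, pair3: str) -> float | None:
        return self.stack.get((pair5, pair3))


def toy_params(
    stack_energy: float = -1.0,
    init_penalty: float = 0.0,
    bulge_open: float = 0.0,
    bulge_extend: float = 0.0,
    internal_open: float = 0.0,
    internal_extend: float = 0.0,
    allow_gu: bool = False,
    max_loop: int = 0,
) -> EnergyParams:
    """Uniform toy parameter set: every canonical stack gets one energy.

    With the defaults (stack -1, init 0, loops forbidden) a perfect
    antiparallel complement of length L scores exactly -(L-1).
    """
    pairs = WC_PAIRS | WOBBLE_PAIRS if allow_gu else WC_PAIRS
    stack = {(p, q): stack_energy for p in pairs for q in pairs}
    return EnergyParams(
        stack=stack,
        init_penalty=init_penalty,
        bulge_open=bulge_open,
        bulge_extend=bulge_extend,
        internal_open=internal_open,
        internal_extend=internal_extend,
        allow_gu=allow_gu,
        max_loop=max_loop,
    )


def _parse_params(lines) -> EnergyParams:
    stack: dict[tuple[str, str], float] = {}
    scalars: dict[str, float] = {}
    allow_gu = True
    max_loop = 10
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        key = cells[0]
        if key == "stack":
            if len(cells) != 4:
                raise ValueError(f"line {lineno}: stack rows need pair, pair, energy")
            p, q, e = cells[1].upper(), cells[2].upper(), float(cells[3])
            if p not in WC_PAIRS | WOBBLE_PAIRS or q not in WC_PAIRS | WOBBLE_PAIRS:
                raise ValueError(f"line {lineno}: unknown base pair {p}/{q}")
            stack[(p, q)] = e
        elif key == "allow_gu":
            allow_gu = cells[1].lower() in {"true", "1", "yes"}
        elif key == "max_loop":
            max_loop = int(cells[1])
        else:
            scalars[key] = float(cells[1])
    known = {"init_penalty", "bulge_open", "bulge_extend", "internal_open", "internal_extend"}
    unknown = set(scalars) - known
    if unknown:
        raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
    return EnergyParams(stack=stack, allow_gu=allow_gu, max_loop=max_loop, **scalars)


def load_params(path: str | Path) -> EnergyParams:
    """Load an energy parameter TSV (see the shipped stack_params.tsv)."""
    with open(path) as fh:
        return _parse_params(fh)


def default_params() -> EnergyParams:
    """The shipped Turner-style parameter set."""
    text = resources.files("tfmir.data").joinpath("stack_params.tsv").read_text()
    return _parse_params(text.splitlines())
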