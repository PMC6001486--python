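"""Text export of operators and superoperator matrices (CSV / JSON).

Matrices round-trip exactly through JSON (17 significant digits) as
shape + [re, im] pairs; CSV export writes one row per matrix row with
re/im column pairs, mainly for debugging.
"""

from __future__ import annotations

import json

import numpy as np

from .liouville import Superoperator
from .operators import SpinOperator
from .spin_system import SpinSystem

__all__ = [
    "matrix_to_csv",
    "matrix_to_json",
    "matrix_from_json",
    "operator_to_json",
    "operator_from_json",
    "superoperator_to_json",
    "superoperator_from_json",
]


def matrix_to_csv(matrix: np.ndarray, path) -> None:
    M = np.asarray(matrix, dtype=complex)
    with open(path, "w") as fh:
        cols = []
        for c in range(M.shape[1]):
            cols += [f"re{c}", f"im{c}"]
        fh.write(",".join(cols) + "\n")
        for row in M:
            cells = []
            for z in row:
                cells += [f"{z.real:.17g}", f"{z.imag:.17g}"]
            fh.write(",".join(cells) + "\n")


def matrix_to_json(matrix: np.ndarray, path=None, **meta):
    M = np.asarray(matrix, dtype=complex)
    payload = {
        "shape": list(M.shape),
        "elements": [[z.real, z.imag] for z in M.reshape(-1)],
        **meta,
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh)
    return payload


def matrix_from_json(source) -> np.ndarray:
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        with open(source) as fh:  # type: ignore[arg-type]
            payload = json.load(fh)
    else:
        payload = source
    shape = tuple(payload["shape"])
    flat = np.array([complex(re, im) for re, im in payload["elements"]])
    return flat.reshape(shape)


def operator_to_json(op: SpinOperator, path=None):
    return matrix_to_json(op.matrix, path, kind="operator", label=op.label)


def operator_from_json(system: SpinSystem, source) -> SpinOperator:
    return SpinOperator(system, matrix_from_json(source))


def superoperator_to_json(sup: Superoperator, path=None):
    return matrix_to_json(sup.matrix, path, kind="superoperator", label=sup.label)


def superoperator_from_json(system: SpinSystem, source) -> Superoperator:
    return Superoperator(system, matrix_from_json(source))
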