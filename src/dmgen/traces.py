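"""Cα trace extraction from PDB files and conversion to distance matrices.

A protein chain is reduced to the ordered 3-D coordinates of its Cα atoms.
Chains are split into contiguous segments wherever a residue lacks a Cα,
residue numbering jumps, or consecutive Cα atoms are further apart than a
chain-break cutoff (an intact backbone places consecutive Cα atoms near
3.8 Å). Segments are cut into non-overlapping fixed-length fragments and each
fragment becomes one symmetric, zero-diagonal Euclidean distance matrix in Å.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field

import gemmi
import numpy as np

#: consecutive-Cα distance above which the chain is considered broken (Å)
CHAIN_BREAK_CUTOFF = 4.5


class PDBFormatError(ValueError):
    """Raised when the input cannot be parsed as PDB."""


@dataclass
class CaTrace:
    """Ordered Cα coordinates of one contiguous chain segment."""

    coords: np.ndarray                    # (n, 3) float64, Å
    source_id: str = ""
    residue_numbers: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("CaTrace coordinates must be finite")
        if len(self.coords) < 1:
            raise ValueError("CaTrace must contain at least one residue")
        if self.residue_numbers is None:
            self.residue_numbers = np.arange(len(self.coords))
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        if len(self.residue_numbers) != len(self.coords):
            raise ValueError("residue_numbers length mismatch")
        if len(self.residue_numbers) > 1 and np.any(np.diff(self.residue_numbers) <= 0):
            raise ValueError("residue_numbers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.coords)


def _pick_ca(residue: gemmi.Residue) -> gemmi.Atom | None:
    """Select the Cα atom of a residue.

    Alternate locations are resolved to the highest occupancy; ties break
    alphabetically by altloc identifier (so 'A' wins over 'B').
    """
    cas = [a for a in residue if a.name == "CA" and a.element.name == "C"]
    if not cas:
        return None
    return min(cas, key=lambda a: (-a.occ, a.altloc or "A"))


def read_ca_traces(pdb_source, break_cutoff: float = CHAIN_BREAK_CUTOFF) -> list[CaTrace]:
    """Extract contiguous Cα trace segments from a PDB file.

    Parameters
    ----------
    pdb_source : path, str of PDB text, or bytes
        PDB-format input. HETATM records and non-first models are ignored.
    break_cutoff : float
        Consecutive-Cα distance (Å) above which a new segment starts.

    Returns
    -------
    list of CaTrace, one per contiguous segment per chain. A file without any
    Cα atoms yields an empty list.
    """
    text = _coerce_pdb_text(pdb_source)
    name = text[1] or "input"
    try:
        structure = gemmi.read_pdb_string(text[0])
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"cannot parse PDB input {name!r}: {exc}") from exc
    if len(structure) == 0:
        return []
    structure.setup_entities()
    pdb_id = structure.name.strip().lower() or os.path.splitext(os.path.basename(name))[0]

    traces: list[CaTrace] = []
    model = structure[0]
    for chain in model:
        coords: list[list[float]] = []
        numbers: list[int] = []

        def flush():
            if coords:
                traces.append(CaTrace(np.array(coords), f"{pdb_id}_{chain.name}",
                                      np.array(numbers)))
                coords.clear()
                numbers.clear()

        prev_num = None
        for residue in chain:
            if residue.het_flag != "A":      # ATOM records only
                continue
            ca = _pick_ca(residue)
            num = residue.seqid.num
            if ca is None:
                flush()
                prev_num = None
                continue
            pos = [ca.pos.x, ca.pos.y, ca.pos.z]
            if coords:
                gap = prev_num is not None and num != prev_num + 1
                dist = np.linalg.norm(np.array(pos) - np.array(coords[-1]))
                if gap or dist > break_cutoff:
                    flush()
            coords.append(pos)
            numbers.append(num)
            prev_num = num
        flush()
    return traces


def _coerce_pdb_text(pdb_source) -> tuple[str, str]:
    if isinstance(pdb_source, bytes):
        return pdb_source.decode("utf-8", errors="replace"), ""
    if isinstance(pdb_source, io.IOBase):
        return pdb_source.read(), ""
    s = str(pdb_source)
    if "\n" in s or not os.path.exists(s):
        if "\n" not in s and not os.path.exists(s):
            raise PDBFormatError(f"no such PDB file: {s!r}")
        return s, ""
    with open(s) as fh:
        return fh.read(), s


def extract_fragments(trace: CaTrace, fragment_length: int = 128) -> list[CaTrace]:
    """Cut a trace into non-overlapping fragments of fixed length.

    Fragments are taken left to right; trailing residues that do not fill a
    full fragment are discarded, so ``floor(len/L)`` fragments are returned.
    """
    if fragment_length < 2:
        raise ValueError("fragment_length must be >= 2")
    n = len(trace) // fragment_length
    out = []
    for k in range(n):
        sl = slice(k * fragment_length, (k + 1) * fragment_length)
        out.append(CaTrace(trace.coords[sl], f"{trace.source_id}_f{k}",
                           trace.residue_numbers[sl]))
    return out


def trace_to_distance_matrix(fragment: CaTrace) -> np.ndarray:
    """Pairwise Euclidean Cα–Cα distance matrix (Å) of a fragment."""
    if len(fragment) < 2:
        raise ValueError("need at least 2 residues for a distance matrix")
    x = fragment.coords
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite coordinates")
    diff = x[:, None, :] - x[None, :, :]
    d = np.sqrt((diff * diff).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return d
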