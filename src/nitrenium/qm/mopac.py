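"""Adapter for an external MOPAC-dialect AM1 program.

Writes a classic MOPAC input deck (keyword line, two comment lines,
Cartesian coordinate block with optimisation flags), runs the executable as
a subprocess and parses the final heat of formation and geometry from the
output file.  Useful for cross-checking the built-in engine against a
reference binary when one is installed; the engine path is supplied
explicitly or via configuration.
"""

from __future__ import annotations

import re
import subprocess
import tempfile
from pathlib import Path
from typing import Sequence

import numpy as np

from .base import QMResult

_SYMBOL = {1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 16: "S", 17: "Cl", 35: "Br"}

_HOF_RE = re.compile(r"FINAL HEAT OF FORMATION\s*=\s*(-?\d+\.\d+)\s*KCAL")


def write_deck(numbers: Sequence[int], coords: np.ndarray, charge: int,
               extra_keywords: str = "") -> str:
    """MOPAC input deck for an AM1 singlet geometry optimisation."""
    keywords = "AM1 PRECISE SINGLET"
    if charge:
        keywords += f" CHARGE={charge:+d}".replace("+", "")
    if extra_keywords:
        keywords += " " + extra_keywords
    lines = [keywords, "generated by nitrenium", ""]
    for z, (x, y, z3) in zip(numbers, np.asarray(coords, dtype=float)):
        sym = _SYMBOL[int(z)]
        lines.append(f"{sym:<3s} {x:12.6f} 1 {y:12.6f} 1 {z3:12.6f} 1")
    return "\n".join(lines) + "\n"


def parse_output(text: str, natoms: int) -> QMResult:
    """Extract the heat of formation and final geometry from MOPAC output."""
    m = _HOF_RE.search(text)
    if m is None:
        return QMResult(converged=False, engine_log=text[-2000:])
    hof = float(m.group(1))
    coords = _parse_final_geometry(text, natoms)
    return QMResult(converged=True, heat_of_formation=hof, coords=coords,
                    engine_log=text[-2000:])


def _parse_final_geometry(text: str, natoms: int) -> np.ndarray | None:
    lines = text.splitlines()
    anchor = None
    for i, ln in enumerate(lines):
        if "CARTESIAN COORDINATES" in ln:
            anchor = i
    if anchor is None:
        return None
    rows = []
    for ln in lines[anchor + 1:]:
        parts = ln.split()
        if len(parts) >= 5 and parts[0].isdigit():
            try:
                rows.append([float(parts[-3]), float(parts[-2]),
                             float(parts[-1])])
            except ValueError:
                continue
        elif rows:
            break
        if len(rows) == natoms:
            break
    if len(rows) != natoms:
        return None
    return np.array(rows)


class MopacEngine:
    """Run an external MOPAC-style binary for each optimisation."""

    def __init__(self, executable: str, timeout: float = 300.0,
                 keep_files: bool = False, scratch: str | None = None):
        exe = Path(executable)
        if not exe.exists():
            raise FileNotFoundError(
                f"MOPAC executable not found at '{executable}'; set the "
                "engine path in the configuration or use the built-in "
                "AM1 engine")
        self.executable = str(exe)
        self.timeout = timeout
        self.keep_files = keep_files
        self.scratch = scratch
        self.fingerprint = f"mopac:{exe.name}"

    def optimize(self, numbers: Sequence[int], coords: np.ndarray,
                 charge: int = 0) -> QMResult:
        deck = write_deck(numbers, coords, charge)
        with tempfile.TemporaryDirectory(dir=self.scratch) as tmp:
            inp = Path(tmp) / "job.mop"
            inp.write_text(deck)
            try:
                subprocess.run([self.executable, str(inp)], cwd=tmp,
                               timeout=self.timeout, capture_output=True,
                               check=False)
            except subprocess.TimeoutExpired:
                return QMResult(converged=False, engine_log="engine timeout")
            out = inp.with_suffix(".out")
            if not out.exists():
                return QMResult(converged=False,
                                engine_log="engine produced no output file")
            return parse_output(out.read_text(), len(numbers))
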