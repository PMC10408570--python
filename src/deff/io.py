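"""Plain-text coordinate and sample I/O: XYZ, PDB (with CRYST1 box), CSV."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .system import Configuration

__all__ = ["write_xyz", "read_xyz", "write_pdb", "read_pdb", "write_samples_csv"]


def write_xyz(path, conf: Configuration, elements, comment: str = "", append: bool = False):
    mode = "a" if append else "w"
    x = conf.coordinates
    with open(path, mode) as fh:
        fh.write(f"{len(x)}\n{comment}\n")
        for el, (a, b, c) in zip(elements, x):
            fh.write(f"{el:<2s} {a:14.8f} {b:14.8f} {c:14.8f}\n")


def read_xyz(path) -> tuple[list[str], Configuration]:
    """Read the first frame of an XYZ file (no box information)."""
    with open(path) as fh:
        n = int(fh.readline())
        fh.readline()
        elements, coords = [], []
        for _ in range(n):
            tok = fh.readline().split()
            elements.append(tok[0])
            coords.append([float(t) for t in tok[1:4]])
    return elements, Configuration(np.asarray(coords))


def write_pdb(path, conf: Configuration, elements, resnames=None):
    """Minimal PDB writer; the CRYST1 record carries the orthorhombic box."""
    x = conf.coordinates
    resnames = resnames or ["MOL"] * len(x)
    with open(path, "w") as fh:
        if conf.box is not None:
            a, b, c = conf.box
            fh.write(f"CRYST1{a:9.3f}{b:9.3f}{c:9.3f}  90.00  90.00  90.00 P 1           1\n")
        for i, (el, (px, py, pz)) in enumerate(zip(elements, x), start=1):
            name = el[:4]
            fh.write(
                f"HETATM{i:5d} {name:<4s}{resnames[i-1][:3]:>4s} A{1:4d}    "
                f"{px:8.3f}{py:8.3f}{pz:8.3f}  1.00  0.00          {el:>2s}\n"
            )
        fh.write("END\n")


def read_pdb(path) -> tuple[list[str], Configuration]:
    elements, coords, box = [], [], None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
            elif line.startswith(("ATOM", "HETATM")):
                coords.append(
                    [float(line[30:38]), float(line[38:46]), float(line[46:54])]
                )
                el = line[76:78].strip() or line[12:16].strip()[:1]
                elements.append(el)
    return elements, Configuration(np.asarray(coords), box)


def write_samples_csv(path, samples) -> None:
    """SampleSet scalar series as `step,energy,volume` CSV."""
    pd.DataFrame(
        {
            "step": np.arange(samples.n_samples),
            "energy": samples.energies,
            "volume": samples.volumes,
        }
    ).to_csv(path, index=False)
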