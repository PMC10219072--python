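"""Reading and writing structures, ensembles, matrices and result tables.

Structures come in as PDB (one C-alpha per protein residue, one P per
nucleotide); ensembles as DCD/XTC trajectories, multi-model PDB, or the
plain-text frame-table format below. All coordinates are Angstrom
internally (MDAnalysis converts XTC's nm on read).

Frame-table format: line 1 is a header of ``chain:label:role`` site tags,
followed by one line per frame holding 3N whitespace-separated floats
(x y z per site, in header order). It exists so fixtures can be produced
by hand or by any language.
"""

from __future__ import annotations

import os
import warnings

import numpy as np

from .model import (
    DEFAULT_DOMAIN_RANGES,
    Domain,
    Ensemble,
    Site,
    SiteModel,
    SiteRole,
    assign_domain,
)

__all__ = [
    "load_structure",
    "load_ensemble",
    "write_matrix",
    "read_matrix",
    "write_table",
    "write_frame_table",
    "read_frame_table",
    "write_reference_pdb",
    "read_config",
    "write_config",
]


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def load_structure(path, role_rules=None, domain_ranges=None) -> SiteModel:
    """Build a SiteModel from a PDB file or a frame-table header.

    ``role_rules`` maps roles to atom names (default: CA for protein
    residues, P for nucleotides). Protein sites come first, then DNA,
    each ordered by label. A residue selected by the rules but missing
    its coarse atom is a hard error naming the residue.
    """
    path = os.fspath(path)
    if domain_ranges is None:
        domain_ranges = DEFAULT_DOMAIN_RANGES
    if path.endswith((".tsv", ".txt", ".ftab")):
        return _site_model_from_frame_table_header(path, domain_ranges)
    return _site_model_from_pdb(path, role_rules, domain_ranges)


_NUCLEOTIDES = {
    "DA", "DT", "DG", "DC", "DU", "A", "T", "G", "C", "U",
    "ADE", "THY", "GUA", "CYT", "URA",
}


def _site_model_from_pdb(path, role_rules, domain_ranges) -> SiteModel:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    ca_name = (role_rules or {}).get("CA", "CA")
    p_name = (role_rules or {}).get("P", "P")
    protein_sites: list[Site] = []
    dna_sites: list[Site] = []
    for res in u.residues:
        is_dna = res.resname.strip() in _NUCLEOTIDES
        want = p_name if is_dna else ca_name
        atoms = res.atoms.select_atoms(f"name {want}")
        if len(atoms) == 0:
            raise ValueError(
                f"residue {res.resname} {res.resid} (chain {res.segid or '?'}) "
                f"has no {want} atom"
            )
        coord = atoms.positions[0].astype(float)
        site = Site(
            site_id=-1,
            label=int(res.resid),
            chain="DNA" if is_dna else "PROT",
            role=SiteRole.P if is_dna else SiteRole.CA,
            domain=Domain.DNA if is_dna else assign_domain(int(res.resid), domain_ranges),
            reference_coords=coord,
        )
        (dna_sites if is_dna else protein_sites).append(site)
    protein_sites.sort(key=lambda s: s.label)
    dna_sites.sort(key=lambda s: s.label)
    return SiteModel(protein_sites + dna_sites)


def _parse_site_tag(tag: str):
    parts = tag.split(":")
    if len(parts) != 3:
        raise ValueError(f"malformed site tag {tag!r} (expected chain:label:role)")
    chain, label, role = parts
    return chain, int(label), SiteRole(role)


def _site_model_from_frame_table_header(path, domain_ranges) -> SiteModel:
    with open(path) as fh:
        header = fh.readline().split()
        if not header:
            raise ValueError(f"{path}: empty frame table")
        first = fh.readline().split()
    coords = np.zeros((len(header), 3))
    if first:
        if len(first) != 3 * len(header):
            raise ValueError(f"{path}: first frame does not hold 3N floats")
        coords = np.array(first, dtype=float).reshape(len(header), 3)
    sites = []
    for i, tag in enumerate(header):
        chain, label, role = _parse_site_tag(tag)
        domain = Domain.DNA if role is SiteRole.P else assign_domain(label, domain_ranges)
        sites.append(Site(-1, label, chain, role, domain, coords[i]))
    return SiteModel(sites)


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def load_ensemble(path, site_model: SiteModel, format: str | None = None) -> Ensemble:
    """Read an ensemble from DCD/XTC/multi-model PDB or a frame table.

    The file must carry exactly ``site_model.n_sites`` sites per frame in
    model order; a mismatch is reported with the offending frame index.
    """
    path = os.fspath(path)
    fmt = (format or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt in ("tsv", "txt", "ftab", "frame-table", "frametable"):
        return read_frame_table(path, site_model)
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if fmt in ("dcd", "xtc"):
            u = mda.Universe(_topology_for(site_model), path)
        else:
            u = mda.Universe(path)
    atoms = u.atoms
    if len(atoms) != site_model.n_sites:
        # full-atom file: extract the coarse sites by role atom name
        atoms = u.select_atoms("name CA P")
    frames = []
    times = []
    for i, ts in enumerate(u.trajectory):
        if len(atoms) != site_model.n_sites:
            raise ValueError(
                f"frame {i}: {len(atoms)} sites, expected {site_model.n_sites}"
            )
        frames.append(atoms.positions.astype(float).copy())
        times.append(float(ts.time))
    return Ensemble(np.array(frames), site_model, times=np.array(times))


def _topology_for(site_model: SiteModel):
    """Minimal in-memory MDAnalysis topology matching the site model."""
    import MDAnalysis as mda

    n = site_model.n_sites
    u = mda.Universe.empty(n, trajectory=True)
    u.add_TopologyAttr("name", [s.role.value for s in site_model.sites])
    u.add_TopologyAttr("resid", list(range(1, n + 1)))
    return u


def write_frame_table(ensemble: Ensemble, path) -> None:
    header = " ".join(
        f"{s.chain}:{s.label}:{s.role.value}" for s in ensemble.site_model.sites
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for frame in ensemble.coords:
            fh.write(" ".join(repr(float(v)) for v in frame.ravel()) + "\n")


def read_frame_table(path, site_model: SiteModel) -> Ensemble:
    n = site_model.n_sites
    frames = []
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != n:
            raise ValueError(
                f"{path}: header has {len(header)} sites, expected {n}"
            )
        for tag, site in zip(header, site_model.sites):
            chain, label, role = _parse_site_tag(tag)
            if (chain, label, role) != (site.chain, site.label, site.role):
                raise ValueError(
                    f"{path}: header site {tag} does not match model site "
                    f"{site.chain}:{site.label}:{site.role.value}"
                )
        for i, line in enumerate(fh):
            vals = line.split()
            if not vals:
                continue
            if len(vals) != 3 * n:
                raise ValueError(f"{path}: frame {i} has {len(vals)} values, expected {3 * n}")
            frames.append(np.array(vals, dtype=float).reshape(n, 3))
    if not frames:
        raise ValueError(f"{path}: no frames")
    return Ensemble(np.array(frames), site_model)


def write_reference_pdb(site_model: SiteModel, path) -> None:
    """Write the reference coordinates as a coarse one-model PDB."""
    with open(path, "w") as fh:
        serial = 1
        for s in site_model.sites:
            resname = "GLY" if s.role is SiteRole.CA else "DA"
            chain = "A" if s.chain == "PROT" else "B"
            x, y, z = s.reference_coords
            name = f" {s.role.value:<3s}"  # columns 13-16, standard padding
            fh.write(
                f"ATOM  {serial:5d} {name:<4s} {resname:<3s} {chain}"
                f"{s.label:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00\n"
            )
            serial += 1
        fh.write("END\n")


# ---------------------------------------------------------------------------
# matrices and tables
# ---------------------------------------------------------------------------

_SENTINEL = "NA"


def write_matrix(matrix, path, labels=None, row_labels=None, col_labels=None) -> None:
    """Write a matrix as TSV with row/column headers (site labels).

    Masked or non-finite entries are written as the sentinel ``NA``.
    Values round-trip bit-identically through :func:`read_matrix`.
    """
    m = np.ma.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("write_matrix expects a 2-D array")
    rows = row_labels if row_labels is not None else labels
    cols = col_labels if col_labels is not None else labels
    rows = list(rows) if rows is not None else list(range(m.shape[0]))
    cols = list(cols) if cols is not None else list(range(m.shape[1]))
    if len(rows) != m.shape[0] or len(cols) != m.shape[1]:
        raise ValueError("label count does not match matrix shape")
    with open(path, "w") as fh:
        fh.write("site\t" + "\t".join(str(c) for c in cols) + "\n")
        for lab, row in zip(rows, m):
            cells = []
            for v in row:
                bad = v is np.ma.masked or not np.isfinite(v)
                cells.append(_SENTINEL if bad else repr(float(v)))
            fh.write(str(lab) + "\t" + "\t".join(cells) + "\n")


def read_matrix(path):
    """Read a matrix written by :func:`write_matrix`.

    Returns ``(matrix, row_labels, col_labels)``; sentinel cells come back
    as a masked array entry.
    """
    with open(path) as fh:
        cols = fh.readline().rstrip("\n").split("\t")[1:]
        rows, data, mask = [], [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            rows.append(parts[0])
            vals = [0.0 if p == _SENTINEL else float(p) for p in parts[1:]]
            data.append(vals)
            mask.append([p == _SENTINEL for p in parts[1:]])
    m = np.ma.masked_array(np.array(data), mask=np.array(mask))
    return m, rows, cols


def write_table(records, path, columns=None) -> None:
    """Write a list of dict records (or a DataFrame) as TSV."""
    import pandas as pd

    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(records)
    if columns is not None:
        df = df[list(columns)]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# flat key=value config
# ---------------------------------------------------------------------------

def read_config(path) -> dict[str, str]:
    cfg: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{ln}: expected key=value, got {line!r}")
            key, val = line.split("=", 1)
            cfg[key.strip()] = val.strip()
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        for key, val in cfg.items():
            fh.write(f"{key}={val}\n")
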