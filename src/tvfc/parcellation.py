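"""ROI -> network assignment tables.

A parcellation fixes two things for the whole pipeline: the canonical
column order of every ROI time-series matrix (the row order of the
config file) and the partition of ROIs into named functional networks,
which defines the blocks used by the intra- and inter-network
variability statistics.

The packaged default covers the 116-parcel AAL atlas assigned to 11
networks (sensorimotor, visual, auditory, default_mode, frontoparietal,
cingulo_opercular, salience, attention, subcortical, thalamus,
cerebellum), with thalamus and cerebellum as standalone networks.  The
assignment is a best-effort, editable config: all downstream code reads
a :class:`Parcellation`, never a hard-coded map.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Parcellation",
    "load_parcellation",
    "write_parcellation",
    "default_parcellation",
    "network_members",
]

_DEFAULT_RESOURCE = "aal116_networks.tsv"


@dataclass(frozen=True)
class Parcellation:
    """Ordered ROI labels and their one-to-one assignment to networks.

    Parameters
    ----------
    roi_labels
        ROI names in canonical (file-row) order; length R.
    networks
        Network name for each ROI, aligned with ``roi_labels``.
    """

    roi_labels: tuple[str, ...]
    networks: tuple[str, ...]
    network_names: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.roi_labels) != len(self.networks):
            raise ValueError("roi_labels and networks must have equal length")
        if len(self.roi_labels) < 2:
            raise ValueError("a parcellation needs at least 2 ROIs")
        seen: set[str] = set()
        for lab in self.roi_labels:
            if lab in seen:
                raise ValueError(f"duplicate ROI label: {lab!r}")
            seen.add(lab)
        for lab, net in zip(self.roi_labels, self.networks):
            if not net:
                raise ValueError(f"ROI {lab!r} has an empty network assignment")
        # network order = first appearance in ROI order
        names: list[str] = []
        for net in self.networks:
            if net not in names:
                names.append(net)
        object.__setattr__(self, "network_names", tuple(names))

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)

    @property
    def n_networks(self) -> int:
        return len(self.network_names)

    def members(self, network: str) -> np.ndarray:
        """0-based ROI indices of ``network``, ascending."""
        if network not in self.network_names:
            raise KeyError(
                f"unknown network {network!r}; valid names: "
                f"{', '.join(self.network_names)}"
            )
        return np.flatnonzero(np.asarray(self.networks) == network)

    def network_pairs(self) -> list[tuple[str, str]]:
        """All unordered network pairs, each pair in lexicographic order,
        pairs sorted lexicographically."""
        names = sorted(self.network_names)
        return [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]

    def labels_checksum(self) -> str:
        """SHA-1 over the ordered ROI labels; guards column alignment."""
        joined = "\n".join(self.roi_labels).encode()
        return hashlib.sha1(joined).hexdigest()


def load_parcellation(path: str | Path) -> Parcellation:
    """Read a parcellation config.

    Two formats are accepted:

    * tab-separated text with a header line and columns
      ``roi_label<TAB>network`` (an optional leading integer index
      column is tolerated);
    * a JSON object mapping ROI label -> network name (insertion order
      is the ROI order).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        mapping = json.loads(text)
        return Parcellation(tuple(mapping.keys()), tuple(mapping.values()))
    labels: list[str] = []
    nets: list[str] = []
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty parcellation file")
    header = [c.strip().lower() for c in lines[0].split("\t")]
    cols = _resolve_columns(header, path)
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) <= max(cols):
            raise ValueError(
                f"{path}:{lineno}: expected at least {max(cols) + 1} "
                f"tab-separated fields, got {len(parts)}: {line!r}"
            )
        labels.append(parts[cols[0]].strip())
        nets.append(parts[cols[1]].strip())
    return Parcellation(tuple(labels), tuple(nets))


def _resolve_columns(header: list[str], path: Path) -> tuple[int, int]:
    """Locate (roi_label, network) columns, tolerating a leading index."""
    try:
        return header.index("roi_label"), header.index("network")
    except ValueError:
        pass
    if len(header) == 2:
        return 0, 1
    if len(header) == 3 and header[0] in ("index", "roi_index", "id"):
        return 1, 2
    raise ValueError(
        f"{path}: unrecognised column layout {header!r}; expected "
        "'roi_label' and 'network' columns"
    )


def write_parcellation(p: Parcellation, path: str | Path) -> None:
    """Write the TSV dialect read by :func:`load_parcellation`."""
    with open(path, "w") as f:
        f.write("roi_label\tnetwork\n")
        for lab, net in zip(p.roi_labels, p.networks):
            f.write(f"{lab}\t{net}\n")


def default_parcellation() -> Parcellation:
    """The packaged 116-ROI AAL / 11-network assignment."""
    ref = resources.files("tvfc.data").joinpath(_DEFAULT_RESOURCE)
    with resources.as_file(ref) as path:
        return load_parcellation(path)


def network_members(p: Parcellation, network: str) -> np.ndarray:
    """Functional alias for :meth:`Parcellation.members`."""
    return p.members(network)
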