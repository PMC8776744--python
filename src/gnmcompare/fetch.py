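"""Thin helper for downloading deposited structures from the PDB.

Kept outside the pipeline core on purpose: the analyses never fetch
anything themselves.  Use this (or any other means) to obtain coordinate
files, then pass paths to the library/CLI.
"""

from __future__ import annotations

import urllib.error
import urllib.request
from pathlib import Path

from .errors import InputError

RCSB_URL = "https://files.rcsb.org/download/{accession}.{ext}"


def fetch_pdb(
    accession: str,
    dest_dir: str | Path = ".",
    fmt: str = "pdb",
    timeout: float = 30.0,
    overwrite: bool = False,
) -> Path:
    """Download one accession (``pdb`` or ``cif``) into ``dest_dir``.

    Returns the local path; raises :class:`InputError` when the archive is
    unreachable (e.g. offline) or the accession does not exist.
    """
    accession = accession.lower()
    ext = {"pdb": "pdb", "cif": "cif", "mmcif": "cif"}[fmt]
    dest = Path(dest_dir) / f"{accession}.{ext}"
    if dest.is_file() and not overwrite:
        return dest
    url = RCSB_URL.format(accession=accession.upper(), ext=ext)
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except (urllib.error.URLError, OSError, ValueError) as e:
        raise InputError(f"cannot fetch {accession!r} from {url}: {e}") from e
    dest.parent.mkdir(parents=True, exist_ok=True)
    dest.write_bytes(data)
    return dest
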