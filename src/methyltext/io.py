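"""Document readers: plain text and MEDLINE-format abstracts."""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Iterator

from Bio import Medline

logger = logging.getLogger("methyltext")

__all__ = ["read_plain_documents", "read_medline"]


def read_plain_documents(paths: Iterable) -> Iterator[tuple[str, str]]:
    """Yield (filename, text) per plain-text file; one document per file.

    Unreadable files are skipped with a warning.
    """
    for p in paths:
        p = Path(p)
        try:
            yield p.name, p.read_text(encoding="utf-8")
        except OSError as exc:
            logger.warning("skipping unreadable document %s: %s", p, exc)


def read_medline(path) -> Iterator[tuple[str, str]]:
    """Yield (PMID, title + abstract) per record of a MEDLINE file."""
    with open(path, encoding="utf-8") as fh:
        for rec in Medline.parse(fh):
            pmid = rec.get("PMID", "unknown")
            title = rec.get("TI", "")
            abstract = rec.get("AB", "")
            text = " ".join(part for part in (title, abstract) if part)
            if text:
                yield pmid, text
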