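"""Filesystem-backed object storage.

Cloud runs keep query batches, manifests and results in buckets; this
package accepts bucket-style locators (``s3://bucket/key``,
``gs://bucket/key``) and maps them onto a local directory tree so the
rest of the code can treat "object storage" uniformly without cloud
credentials.  Plain filesystem paths pass through untouched.
"""

from __future__ import annotations

import os
import shutil
from pathlib import Path

_SCHEMES = ("s3://", "gs://")

#: environment variable overriding where bucket-style locators are rooted
STORE_ROOT_ENV = "BATCHBLAST_STORE_ROOT"


def is_bucket_locator(locator: str) -> bool:
    return locator.startswith(_SCHEMES)


class ObjectStore:
    """Resolve locators to local paths and perform object I/O.

    Parameters
    ----------
    root:
        Directory under which bucket-style locators are materialised as
        ``<root>/<scheme>/<bucket>/<key>``.  Defaults to the
        ``BATCHBLAST_STORE_ROOT`` environment variable, else
        ``./.batchblast-store``.
    """

    def __init__(self, root: str | os.PathLike | None = None):
        if root is None:
            root = os.environ.get(STORE_ROOT_ENV, ".batchblast-store")
        self.root = Path(root)

    def resolve(self, locator: str) -> Path:
        """Map a locator to a concrete local path (no I/O)."""
        for scheme in _SCHEMES:
            if locator.startswith(scheme):
                rest = locator[len(scheme):]
                if not rest.strip("/"):
                    raise ValueError(f"empty bucket locator: {locator!r}")
                return self.root / scheme[:2] / rest.strip("/")
        return Path(locator)

    def open_read(self, locator: str, mode: str = "rb"):
        path = self.resolve(locator)
        if not path.exists():
            raise FileNotFoundError(f"object not found: {locator}")
        return open(path, mode)

    def write_bytes(self, locator: str, data: bytes) -> Path:
        """Atomic write: temp file in the destination directory, then rename."""
        path = self.resolve(locator)
        path.parent.mkdir(parents=True, exist_ok=True)
        tmp = path.with_name(path.name + ".tmp")
        tmp.write_bytes(data)
        os.replace(tmp, path)
        return path

    def write_text(self, locator: str, text: str) -> Path:
        return self.write_bytes(locator, text.encode())

    def read_bytes(self, locator: str) -> bytes:
        with self.open_read(locator) as fh:
            return fh.read()

    def read_text(self, locator: str) -> str:
        return self.read_bytes(locator).decode()

    def exists(self, locator: str) -> bool:
        return self.resolve(locator).exists()

    def join(self, locator: str, *parts: str) -> str:
        """Join key components onto a locator, preserving its scheme."""
        if is_bucket_locator(locator):
            return locator.rstrip("/") + "/" + "/".join(p.strip("/") for p in parts)
        return str(Path(locator).joinpath(*parts))

    def list_objects(self, locator: str) -> list[str]:
        """Names of objects directly under a prefix (empty if absent)."""
        path = self.resolve(locator)
        if not path.is_dir():
            return []
        return sorted(p.name for p in path.iterdir() if p.is_file())

    def delete_prefix(self, locator: str) -> None:
        """Remove every object under a prefix; missing prefixes are a no-op."""
        path = self.resolve(locator)
        if path.is_dir():
            shutil.rmtree(path)
        elif path.exists():
            path.unlink()
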