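"""Registry identifiers (urn:uuid scheme)."""

from __future__ import annotations

import re
from dataclasses import dataclass

_URN_UUID = re.compile(
    r"^urn:uuid:[0-9a-f]{8}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{4}-[0-9a-f]{12}$"
)


@dataclass(frozen=True)
class Identifier:
    """A registry-minted identifier, stable across updates of a record."""

    value: str
    scheme: str = "uuid_urn"

    def __post_init__(self) -> None:
        if self.scheme == "uuid_urn" and not _URN_UUID.match(self.value):
            raise ValueError(f"not a urn:uuid identifier: {self.value!r}")

    def __str__(self) -> str:
        return self.value
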