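"""The Specimen: one embryo's spine plus ribs, the unit of all measurement."""

from __future__ import annotations

import dataclasses

from .ribs import Rib
from .spine import Spine

__all__ = ["Specimen"]


@dataclasses.dataclass
class Specimen:
    spine: Spine
    ribs: list[Rib] = dataclasses.field(default_factory=list)

    @property
    def specimen_id(self) -> str:
        return self.spine.specimen_id

    @property
    def group(self) -> str:
        return self.spine.group

    @property
    def stage(self) -> int:
        return self.spine.stage
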