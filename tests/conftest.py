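from datetime import datetime, timedelta, timezone

import pytest

from headachekit.records import (
    AppVersion,
    AttackRegistration,
    Intensity,
    Location,
)

UTC = timezone.utc
T0 = datetime(2021, 1, 1, 10, 0, tzinfo=UTC)


@pytest.fixture
def make_attack():
    """Attack factory with v1 defaults (empty sets allowed) at a fixed time."""

    def factory(minutes=45, intensity=1, **kwargs):
        fields = dict(
            patient_id="p000",
            start=T0,
            end=T0 + timedelta(minutes=minutes),
            intensity=Intensity(intensity),
            app_version=AppVersion.V1,
        )
        fields.update(kwargs)
        if "locations" in fields:
            fields["locations"] = frozenset(
                Location.from_code(z) if isinstance(z, str) else z for z in fields["locations"]
            )
        return AttackRegistration(**fields)

    return factory
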