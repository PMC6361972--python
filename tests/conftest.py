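import pytest

from emtscreen.io import PlateLayout, WellRecord, WellRole


@pytest.fixture
def small_layout() -> PlateLayout:
    """One plate: 3 vehicle, 3 positive-control and 2 compound wells."""
    wells = {
        "A01": WellRole("vehicle"),
        "B01": WellRole("vehicle"),
        "C01": WellRole("vehicle"),
        "A12": WellRole("positive_control", concentration=350.0,
                        concentration_unit="ug/ml"),
        "B12": WellRole("positive_control", concentration=350.0,
                        concentration_unit="ug/ml"),
        "C12": WellRole("positive_control", concentration=350.0,
                        concentration_unit="ug/ml"),
        "A02": WellRole("compound", compound_id="CPD1", concentration=1000.0),
        "B02": WellRole("compound", compound_id="CPD2", concentration=1000.0),
    }
    return PlateLayout("P1", wells)


def records_for(layout: PlateLayout, per_channel_totals: dict) -> list[WellRecord]:
    """Expand per-(well, channel) totals into single-field WellRecords."""
    return [
        WellRecord(layout.plate_id, well, channel, 1, int(total))
        for (well, channel), total in per_channel_totals.items()
    ]
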