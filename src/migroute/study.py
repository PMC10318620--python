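"""Published study reference values.

The field study tagged 289 songbirds of seven species at German North Sea
stopover sites and classified each bird's fate from the receiver network:
detected offshore flight, detected onshore flight, departure detected from
stopover signal loss only (routing unknown), or not detected (tag loss,
predation, battery end).  These printed per-species counts, together with a
handful of published posterior estimates, are inputs for bookkeeping
identities and for calibrating the synthetic-data generator; nothing in the
modelling code depends on them.
"""

from __future__ import annotations

import pandas as pd

# Per-species fate counts of all radio-tagged individuals.
OBSERVED_FATES = pd.DataFrame(
    [
        # species, group, tag, offshore, onshore, departed (route unknown), not detected, tagged
        ("Dunnock", "short", "NTQB", 7, 8, 1, 17, 33),
        ("Eurasian Blackbird", "short", "ACT", 9, 6, 10, 10, 35),
        ("Song Thrush", "short", "ACT", 3, 6, 8, 12, 29),
        ("Redwing", "short", "ACT", 0, 3, 8, 8, 19),
        ("Blackcap", "short", "NTQB", 11, 23, 15, 33, 82),
        ("Garden Warbler", "long", "NTQB", 7, 27, 4, 13, 51),
        ("Northern Wheatear", "long", "NTQB", 12, 4, 12, 12, 40),
    ],
    columns=[
        "species",
        "distance_group",
        "tag_type",
        "offshore",
        "onshore",
        "departed",
        "not_detected",
        "tagged",
    ],
)

# Published posterior estimates (posterior means) used for arithmetic
# identities and as calibration anchors for the synthetic generator.
REPORTED = {
    "mean_departure_probability": 0.183,
    "departure_probability_thrushes": 0.074,
    "departure_probability_garden_warbler": 0.374,
    "offshore_flights_estimated": 99.0,
    "offshore_proportion": 0.538,
    "stopover_days_short": 10.7,
    "stopover_days_long": 3.3,
    "stopover_contrast_days": 7.4,
    "departure_time_route_contrast": 0.046,  # fraction of night length
    "offshore_probability_garden_warbler": 0.291,
    "offshore_probability_northern_wheatear": 0.809,
    "detection_offshore_reported": 0.50,
    "detection_onshore_reported": 0.95,
    "rain_nights_fraction": 10 / 128,
    "mean_night_length_hours": 9.3,
}


def fate_totals() -> dict:
    """Column sums of the fate table plus derived bookkeeping counts."""
    t = OBSERVED_FATES
    offshore = int(t["offshore"].sum())
    onshore = int(t["onshore"].sum())
    departed = int(t["departed"].sum())
    not_detected = int(t["not_detected"].sum())
    tagged = int(t["tagged"].sum())
    return {
        "offshore": offshore,
        "onshore": onshore,
        "unrouted_departures": departed,
        "not_detected": not_detected,
        "tagged": tagged,
        "flights": offshore + onshore,
        "modeled_individuals": offshore + onshore + departed,
    }
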