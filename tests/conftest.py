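import json

import pytest

from wearharmonize.harmonize import UnifiedSleepRecord
from wearharmonize.vendor_ingest import RecordIdentity


@pytest.fixture
def microsoft_segment_json() -> str:
    """A single vendor segment in the Microsoft dialect (one restless-sleep
    interval of 4 min 57 s with an HR summary)."""
    return json.dumps(
        {
            "dayId": "2015-09-17T00:00:00.000+00:00",
            "sleepType": "RestlessSleep",
            "segmentId": "NumberLong(635780414429706039)",
            "startTime": "2015-09-16T23:04:02.970+00:00",
            "endTime": "2015-09-16T23:08:59.970+00:00",
            "duration": "PT4M57S",
            "heartRateSummary": {
                "period": "Segment",
                "averageHeartRate": 78,
                "peakHeartRate": 85,
                "lowestHeartRate": 67,
            },
            "segmentType": "Sleep",
        }
    )


@pytest.fixture
def reference_night_record() -> UnifiedSleepRecord:
    """A unified record matching the documented worked night: 394 minutes
    (86 awake / 221 light / 87 relaxed), 01:26:18 -> 08:00:48, 11 min to
    sleep, HR minimum 56, mean skin temperature 34.56."""
    n = 394
    awake = [0] * n
    light = [0] * n
    relaxed = [0] * n
    # layout: 11 min onset latency, then sleep with the remaining awake
    # minutes spread as one interior block, relaxed in the middle
    for i in range(11):
        awake[i] = 1
    for i in range(11, 150):
        light[i] = 1
    for i in range(150, 225):
        awake[i] = 1
    for i in range(225, 312):
        relaxed[i] = 1
    for i in range(312, 394):
        light[i] = 1
    hr = [64] * n
    hr[200] = 56
    return UnifiedSleepRecord(
        identity=RecordIdentity(
            record_id="ref-night",
            student_id="student-ref",
            date=1437523200000,
            device="Microsoft_Api",
        ),
        date_string="2015-07-22",
        total_time_data=394,
        time_to_sleep_data=11,
        temp_mean=34.56,
        hr_min=56,
        num_awake=9,
        awake=86,
        light=221,
        relaxed=87,
        sleep_efficiency=78,
        efficiency_proposal=78,
        start_hour="01:26:18",
        end_hour="08:00:48",
        total_time="06:34:30",
        time_to_sleep="00:11:24",
        minutes_awake=awake,
        minutes_light=light,
        minutes_relaxed=relaxed,
        minutes_time=[str(1437523200000 + 60000 * i) for i in range(n)],
        minutes_hr=hr,
    )
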