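import pytest

from echolv.annotation import Annotation, Dataset, FrameRecord, KeypointName, Phase


@pytest.fixture
def frame640() -> FrameRecord:
    return FrameRecord(study_id="S1", frame_id="F1", image_path="",
                       height_px=480, width_px=640,
                       spacing_x_cm=0.02, spacing_y_cm=0.02, phase=Phase.ED)


@pytest.fixture
def collinear_annotation(frame640) -> Annotation:
    return Annotation(
        frame_id="F1", rater_id="E00", repeat_index=1,
        points={
            KeypointName.SEPT_ANT: (100.0, 100.0),
            KeypointName.SEPT_POST: (110.0, 100.0),
            KeypointName.FW_ANT: (190.0, 100.0),
            KeypointName.FW_POST: (200.0, 100.0),
        })


@pytest.fixture
def small_dataset(frame640, collinear_annotation) -> Dataset:
    return Dataset(frames=[frame640], annotations=[collinear_annotation])


def make_multistudy_dataset(n_studies: int, frames_per_study: int = 2) -> Dataset:
    frames = []
    for s in range(n_studies):
        for f in range(frames_per_study):
            frames.append(FrameRecord(
                study_id=f"S{s:03d}", frame_id=f"S{s:03d}_F{f}", image_path="",
                height_px=100, width_px=100, spacing_x_cm=0.02, spacing_y_cm=0.02,
                phase=Phase.ED if f % 2 == 0 else Phase.ES))
    return Dataset(frames=frames, annotations=[])
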