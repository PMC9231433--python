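import pytest

from freewheel import (
    GestureTemplateParams,
    SignalTrace,
    condition_and_window,
    gen_gesture_dataset,
    train_gesture_ann,
)


def conditioned_dataset(n_per_class: int, template_seed: int = 0):
    """Generate and filter a balanced labelled gesture dataset."""
    raw = gen_gesture_dataset(n_per_class, GestureTemplateParams(seed=template_seed))
    return [
        condition_and_window(
            SignalTrace(w.left, channel_id="left"),
            SignalTrace(w.right, channel_id="right"),
            label=w.label,
        )
        for w in raw
    ]


@pytest.fixture(scope="session")
def small_dataset():
    """10 windows per class: enough signal to train on, fast to generate."""
    return conditioned_dataset(10)


@pytest.fixture(scope="session")
def trained_model(small_dataset):
    model, accuracy = train_gesture_ann(small_dataset, train_seed=0)
    return model, accuracy
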