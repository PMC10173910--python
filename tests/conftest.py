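import pytest

from edcbridge import convert_instrument
from edcbridge import fixtures as fx
from edcbridge.store import RedcapStore

CREDENTIALS = ("processor", "s3cret")


@pytest.fixture
def toy_project():
    return fx.make_toy_project(1)


def provision(store: RedcapStore, project: fx.ToyProject, project_id: str = "toy"):
    """Register the toy project end to end: project, form dictionary,
    participant metadata, rules, visits, one alert recipient."""
    store.create_project(
        project_id,
        "Toy project",
        username=CREDENTIALS[0],
        password=CREDENTIALS[1],
        reference_field=project.reference_field,
    )
    dd = convert_instrument(project.instrument, project.instrument.name)
    store.register_form(project_id, dd, is_first=True)
    store.set_field_metadata(
        project_id,
        project.instrument.name,
        project.participant_field,
        participant_id=True,
        identifier=True,
    )
    for rule in project.rules:
        store.add_rule(
            rule.rule_id, project_id, rule.form, rule.field, rule.rule_type, rule.params
        )
    for cfg in project.visit_configs:
        store.add_visit_config(
            project_id, cfg.event_name, cfg.day_offset, cfg.window_after, cfg.linked_forms
        )
    store.add_alert_recipient(project_id, "team@example.org", "email")
    return store


@pytest.fixture
def store(toy_project):
    s = RedcapStore()
    provision(s, toy_project)
    yield s
    s.close()
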