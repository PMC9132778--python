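# Hand Hygiene Self-Assessment Framework — structural encoding.
#
# This file reproduces the *structure* of the WHO HHSAF 2010 instrument:
# 27 indicators, each worth 10-50 points at its maximum option, grouped into
# the five Multimodal Hand Hygiene Improvement Strategy elements of 100
# points each, for a 500-point total. Question wording and option labels are
# paraphrases written for this package, not a verbatim reproduction of the
# WHO questionnaire.
version_label: hhsaf-2010-structure-v1
elements:
  - element_id: system_change
    name: System Change
    indicators:
      - indicator_id: sc_1
        question: Is alcohol-based hand rub available at the point of care?
        options:
          - {label: not_available, points: 0}
          - {label: some_wards, points: 15}
          - {label: facility_wide, points: 30}
      - indicator_id: sc_2
        question: Is the sink-to-bed ratio at least 1 to 10 in all wards?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 10}
      - indicator_id: sc_3
        question: Is a continuous supply of clean running water available?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 10}
      - indicator_id: sc_4
        question: Is there a dedicated budget for continuous procurement of alcohol-based hand rub?
        options:
          - {label: none, points: 0}
          - {label: intermittent, points: 15}
          - {label: continuous, points: 30}
      - indicator_id: sc_5
        question: Are soap and single-use towels available at every sink?
        options:
          - {label: rarely, points: 0}
          - {label: mostly, points: 10}
          - {label: always, points: 20}
  - element_id: training_education
    name: Training and Education
    indicators:
      - indicator_id: te_1
        question: How often do health-care workers receive hand hygiene training?
        options:
          - {label: never, points: 0}
          - {label: occasionally, points: 10}
          - {label: at_least_yearly, points: 25}
      - indicator_id: te_2
        question: Is hand hygiene training mandatory for new employees?
        options:
          - {label: "no", points: 0}
          - {label: some_categories, points: 10}
          - {label: all_staff, points: 25}
      - indicator_id: te_3
        question: Is a dedicated budget available for hand hygiene training?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 20}
      - indicator_id: te_4
        question: Are trainers with validated hand hygiene competence available?
        options:
          - {label: none, points: 0}
          - {label: external_only, points: 10}
          - {label: in_house, points: 20}
      - indicator_id: te_5
        question: Is a record kept of who has completed training?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 10}
  - element_id: evaluation_feedback
    name: Evaluation and Feedback
    indicators:
      - indicator_id: ef_1
        question: Are periodic audits of hand hygiene infrastructure performed?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
      - indicator_id: ef_2
        question: How often is hand hygiene compliance evaluated by direct observation?
        options:
          - {label: never, points: 0}
          - {label: at_least_yearly, points: 10}
          - {label: at_least_quarterly, points: 25}
      - indicator_id: ef_3
        question: Is alcohol-based hand rub consumption monitored regularly?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
      - indicator_id: ef_4
        question: Was overall compliance above 60 percent in the most recent observation period?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
      - indicator_id: ef_5
        question: What feedback do health-care workers receive on hand hygiene performance?
        options:
          - {label: none, points: 0}
          - {label: immediate_only, points: 10}
          - {label: immediate_and_systematic, points: 20}
      - indicator_id: ef_6
        question: Are results fed back systematically to facility leadership?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 10}
  - element_id: reminders_workplace
    name: Reminders in the Workplace
    indicators:
      - indicator_id: rw_1
        question: Are posters explaining the indications for hand hygiene displayed?
        options:
          - {label: none, points: 0}
          - {label: some_wards, points: 15}
          - {label: all_wards, points: 30}
      - indicator_id: rw_2
        question: Are posters explaining correct hand-rubbing technique displayed?
        options:
          - {label: none, points: 0}
          - {label: some_wards, points: 10}
          - {label: all_wards, points: 20}
      - indicator_id: rw_3
        question: Are posters explaining correct hand-washing technique displayed?
        options:
          - {label: none, points: 0}
          - {label: some_wards, points: 10}
          - {label: all_wards, points: 20}
      - indicator_id: rw_4
        question: Are posters audited and replaced on a regular schedule?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
      - indicator_id: rw_5
        question: Are other workplace reminders used, such as leaflets or screen savers?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
  - element_id: safety_climate
    name: Institutional Safety Climate
    indicators:
      - indicator_id: isc_1
        question: Is there a hand hygiene team or committee?
        options:
          - {label: none, points: 0}
          - {label: informal, points: 10}
          - {label: formal_with_meetings, points: 20}
      - indicator_id: isc_2
        question: Has facility leadership made a visible commitment to hand hygiene?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
      - indicator_id: isc_3
        question: Have institutional hand hygiene targets been established?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
      - indicator_id: isc_4
        question: Are hand hygiene role models and champions identified in the wards?
        options:
          - {label: none, points: 0}
          - {label: champions_only, points: 10}
          - {label: role_models_and_champions, points: 20}
      - indicator_id: isc_5
        question: Is there a formalised programme of patient engagement in hand hygiene?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
      - indicator_id: isc_6
        question: Are initiatives in place to support personal accountability for hand hygiene?
        options:
          - {label: "no", points: 0}
          - {label: "yes", points: 15}
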