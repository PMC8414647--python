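IGHJ4*02:
  reading_frame_offset: 0
  regions:
    FR4:
    - 15
    - 33
  type: J
IGHJ6*02:
  reading_frame_offset: 0
  regions:
    FR4:
    - 15
    - 33
  type: J
IGHV1-2*01:
  reading_frame_offset: 0
  regions:
    CDR1:
    - 30
    - 45
    CDR2:
    - 60
    - 75
    FR1:
    - 0
    - 30
    FR2:
    - 45
    - 60
    FR3:
    - 75
    - 105
  type: V
IGHV3-7*01:
  reading_frame_offset: 0
  regions:
    CDR1:
    - 30
    - 45
    CDR2:
    - 60
    - 75
    FR1:
    - 0
    - 30
    FR2:
    - 45
    - 60
    FR3:
    - 75
    - 105
  type: V
IGHV4-34*01:
  reading_frame_offset: 0
  regions:
    CDR1:
    - 30
    - 45
    CDR2:
    - 60
    - 75
    FR1:
    - 0
    - 30
    FR2:
    - 45
    - 60
    FR3:
    - 75
    - 105
  type: V
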