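# GDF2-subset binary layout

`biosigkit` reads and writes a documented subset of GDF version 2. The file
consists of five components, in order:

    [fixed header: 256 bytes]
    [variable header: 256 bytes per channel]
    [TLV header: optional, variable length]
    [data records]
    [event table]

All multi-byte numeric fields are **little-endian**. Text fields are ASCII,
NUL-padded on the right. The version field is plain `char` text at byte 0 so
that format detection needs only the leading bytes of the file.

## Fixed header (header 1) — 256 bytes, mandatory

| offset | size | type    | field              | notes                                    |
|--------|------|---------|--------------------|------------------------------------------|
| 0      | 8    | char[8] | version_id         | `"GDF 2.20"`                             |
| 8      | 64   | char[64]| recording_id       | free text                                |
| 72     | 64   | char[64]| patient_info       | free text (gender, age etc. optional)    |
| 136    | 8    | float64 | start_datetime     | seconds since the Unix epoch (UTC)       |
| 144    | 4    | uint32  | n_channels         | may be 0 (pure event file)               |
| 148    | 8    | uint64  | n_records          |                                          |
| 156    | 4    | uint32  | samples_per_record | reference rate (event-table time base)   |
| 160    | 8    | float64 | sampling_rate      | Hz, reference rate                       |
| 168    | 8    | uint64  | tlv_length         | total byte length of header 3 (0 = none) |
| 176    | 8    | uint64  | n_events           |                                          |
| 184    | 1    | uint8   | event_mode         | 1 = (position, code); 3 adds (channel, duration) |
| 185    | 71   | —       | reserved           | zeros                                    |

## Variable header (header 2) — 256 bytes per channel

Empty (length 0) when `n_channels == 0`.

| offset | size | type     | field              | notes                           |
|--------|------|----------|--------------------|----------------------------------|
| 0      | 16   | char[16] | label              |                                  |
| 16     | 16   | char[16] | physical_dimension | unit name, e.g. `uV`             |
| 32     | 8    | float64  | physical_min       |                                  |
| 40     | 8    | float64  | physical_max       | must exceed physical_min         |
| 48     | 8    | int64    | digital_min        |                                  |
| 56     | 8    | int64    | digital_max        | must exceed digital_min          |
| 64     | 4    | uint32   | sample_type        | GDF type code: 3 = int16, 16 = float32 |
| 68     | 4    | uint32   | samples_per_record | per-channel rate allowed         |
| 72     | 184  | —        | reserved           | zeros                            |

Calibration is affine per channel:

    gain     = (physical_max - physical_min) / (digital_max - digital_min)
    offset   = physical_min - gain * digital_min
    physical = digital * gain + offset

## TLV header (header 3) — optional

A sequence of tag-length-value blobs occupying exactly `tlv_length` bytes:

| size | type   | field |
|------|--------|-------|
| 1    | uint8  | tag   |
| 4    | uint32 | length (bytes of value) |
| n    | bytes  | value |

Tags are carried opaquely; no tag semantics are interpreted.

## Data records

`n_records` records. Each record holds, for every channel in header order,
`samples_per_record[ch]` raw digital samples of that channel's `sample_type`.
Channels with different `samples_per_record` therefore have different
sampling rates; a channel's rate is
`samples_per_record[ch] * sampling_rate / samples_per_record(header1)`.

## Event table

`n_events` entries at the end of the file, stored as parallel arrays:

    positions: uint32 × n_events   (0-based sample index on the reference rate)
    codes:     uint16 × n_events
    [mode 3 only]
    channels:  uint16 × n_events   (0xFFFF = all channels)
    durations: uint32 × n_events   (samples)

Positions are sorted nondecreasing.
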