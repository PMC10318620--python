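# migroute 0.1.0 simulate config=d07668e785
day,sunset,sunrise
2021-04-01,2021-04-01 19:00:00,2021-04-02 05:00:00
2021-04-02,2021-04-02 19:00:00,2021-04-03 05:00:00
2021-04-03,2021-04-03 19:00:00,2021-04-04 05:00:00
2021-04-04,2021-04-04 19:00:00,2021-04-05 05:00:00
2021-04-05,2021-04-05 19:00:00,2021-04-06 05:00:00
2021-04-06,2021-04-06 19:00:00,2021-04-07 05:00:00
2021-04-07,2021-04-07 19:00:00,2021-04-08 05:00:00
2021-04-08,2021-04-08 19:00:00,2021-04-09 05:00:00
2021-04-09,2021-04-09 19:00:00,2021-04-10 05:00:00
2021-04-10,2021-04-10 19:00:00,2021-04-11 05:00:00
2021-04-11,2021-04-11 19:00:00,2021-04-12 05:00:00
2021-04-12,2021-04-12 19:00:00,2021-04-13 05:00:00
2021-04-13,2021-04-13 19:00:00,2021-04-14 05:00:00
2021-04-14,2021-04-14 19:00:00,2021-04-15 05:00:00
2021-04-15,2021-04-15 19:00:00,2021-04-16 05:00:00
2021-04-16,2021-04-16 19:00:00,2021-04-17 05:00:00
2021-04-17,2021-04-17 19:00:00,2021-04-18 05:00:00
2021-04-18,2021-04-18 19:00:00,2021-04-19 05:00:00
2021-04-19,2021-04-19 19:00:00,2021-04-20 05:00:00
2021-04-20,2021-04-20 19:00:00,2021-04-21 05:00:00
2021-04-21,2021-04-21 19:00:00,2021-04-22 05:00:00
2021-04-22,2021-04-22 19:00:00,2021-04-23 05:00:00
2021-04-23,2021-04-23 19:00:00,2021-04-24 05:00:00
2021-04-24,2021-04-24 19:00:00,2021-04-25 05:00:00
2021-04-25,2021-04-25 19:00:00,2021-04-26 05:00:00
2021-04-26,2021-04-26 19:00:00,2021-04-27 05:00:00
2021-04-27,2021-04-27 19:00:00,2021-04-28 05:00:00
2021-04-28,2021-04-28 19:00:00,2021-04-29 05:00:00
2021-04-29,2021-04-29 19:00:00,2021-04-30 05:00:00
2021-04-30,2021-04-30 19:00:00,2021-05-01 05:00:00
2021-05-01,2021-05-01 19:00:00,2021-05-02 05:00:00
2021-05-02,2021-05-02 19:00:00,2021-05-03 05:00:00
2021-05-03,2021-05-03 19:00:00,2021-05-04 05:00:00
2021-05-04,2021-05-04 19:00:00,2021-05-05 05:00:00
2021-05-05,2021-05-05 19:00:00,2021-05-06 05:00:00
2021-05-06,2021-05-06 19:00:00,2021-05-07 05:00:00
2021-05-07,2021-05-07 19:00:00,2021-05-08 05:00:00
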