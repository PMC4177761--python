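ec_number	Bacteria	Archaea	Eukarya
5.4.2.2	widely	widely	widely
5.4.2.7	partially	absent	absent
2.7.6.1	widely	widely	widely
2.4.2.14	widely	widely	widely
6.3.4.13	widely	widely	widely
2.1.2.2	widely	widely	widely
6.3.5.3	widely	widely	widely
6.3.3.1	widely	widely	widely
6.3.4.18	widely	widely	widely
5.4.99.18	widely	widely	partially
4.1.1.21	absent	absent	widely
6.3.2.6	widely	widely	widely
4.3.2.2	widely	widely	widely
2.1.2.3	widely	partially	widely
3.5.4.10	widely	partially	widely
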