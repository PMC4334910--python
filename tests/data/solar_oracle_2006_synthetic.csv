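date,nautical_dawn,civil_dawn,sunrise,sunset,civil_dusk,nautical_dusk
2006-01-15,06:46:35,07:27:30,08:05:00,16:34:27,17:11:59,17:52:54
2006-02-15,06:09:34,06:47:48,07:21:36,17:27:22,18:01:15,18:39:33
2006-03-15,05:12:58,05:51:06,06:23:37,18:15:03,18:47:41,19:25:57
2006-04-15,03:58:30,04:41:13,05:15:50,19:05:12,19:40:00,20:23:00
2006-05-15,02:47:30,03:41:27,04:21:37,19:51:58,20:32:22,21:26:52
2006-06-15,02:03:13,03:11:26,03:57:04,20:24:09,21:09:51,22:18:15
2006-07-15,02:30:45,03:31:47,04:14:51,20:16:25,20:59:19,21:59:46
2006-08-15,03:34:55,04:21:30,04:58:09,19:29:41,20:06:07,20:52:20
2006-09-15,04:33:10,05:12:36,05:45:35,18:23:40,18:56:34,19:35:47
2006-10-15,05:21:54,05:59:48,06:32:52,17:17:46,17:50:47,18:28:36
2006-11-15,06:09:00,06:48:56,07:25:04,16:23:41,16:59:48,17:39:40
2006-12-15,06:43:40,07:25:47,08:04:53,16:05:31,16:44:38,17:26:44
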